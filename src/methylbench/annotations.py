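"""Labeled genomic intervals: CpG islands/shores/shelves and gene features.

Island flanks follow the usual convention: shores are the 2 kb regions on
either side of an island, shelves the next 2 kb beyond the shores. Gene
models yield a TSS, a promoter (1 kb upstream of the TSS), an up5kb band
(the 5 kb upstream of the promoter), UTRs, exons and introns. Feature
labels are resolved by a fixed precedence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SHORE_BP = 2000
SHELF_BP = 2000
PROMOTER_BP = 1000
UP5KB_BP = 5000

#: highest wins when a site falls in several features
FEATURE_PRECEDENCE = ["promoter", "utr5", "exon", "intron", "utr3", "up5kb"]
ISLAND_PRECEDENCE = ["island", "shore", "shelf"]


def _merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent intervals per chromosome (membership-preserving)."""
    if len(df) == 0:
        return df.copy()
    out = []
    for chrom, grp in df.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cs, ce = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= ce:
                ce = max(ce, e)
            else:
                out.append((chrom, cs, ce))
                cs, ce = s, e
        out.append((chrom, cs, ce))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def _membership(intervals: pd.DataFrame, chroms: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Vectorized point-in-interval test against merged intervals."""
    member = np.zeros(len(pos), dtype=bool)
    if len(intervals) == 0:
        return member
    for chrom, grp in intervals.groupby("chrom", sort=False):
        sel = chroms == chrom
        if not sel.any():
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        idx = np.searchsorted(starts, pos[sel], side="right") - 1
        ok = idx >= 0
        hit = np.zeros(sel.sum(), dtype=bool)
        hit[ok] = pos[sel][ok] < ends[idx[ok]]
        member[sel] = hit
    return member


def _clip_to_bounds(df: pd.DataFrame, chrom_sizes: dict[str, int] | None, what: str) -> pd.DataFrame:
    df = df[df["end"] > df["start"]].copy()
    if chrom_sizes:
        sizes = df["chrom"].map(chrom_sizes)
        over = (df["start"] < 0) | (df["end"] > sizes.fillna(np.inf))
        if over.any():
            warnings.warn(f"{int(over.sum())} {what} interval(s) clipped to chromosome bounds")
        df["start"] = df["start"].clip(lower=0)
        df.loc[sizes.notna(), "end"] = np.minimum(
            df.loc[sizes.notna(), "end"], sizes[sizes.notna()].astype(np.int64)
        )
        df = df[df["end"] > df["start"]]
    return df.reset_index(drop=True)


@dataclass
class AnnotationSet:
    """Island and gene interval tables plus the derived label tracks.

    ``islands`` must be non-overlapping intervals (chrom, start, end).
    ``genes`` needs chrom, start, end, strand and optionally name/exon
    structure; derived features are computed at construction.
    """

    islands: pd.DataFrame
    genes: pd.DataFrame
    chrom_sizes: dict[str, int] | None = None
    feature_tracks: dict[str, pd.DataFrame] = field(default_factory=dict, repr=False)
    island_tracks: dict[str, pd.DataFrame] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.islands = _clip_to_bounds(
            self.islands[["chrom", "start", "end"]].astype({"start": np.int64, "end": np.int64}),
            self.chrom_sizes, "island",
        )
        self._build_island_tracks()
        self._build_feature_tracks()

    def _build_island_tracks(self):
        isl = _merge_intervals(self.islands)
        shores = pd.concat(
            [
                isl.assign(start=isl["start"] - SHORE_BP, end=isl["start"]),
                isl.assign(start=isl["end"], end=isl["end"] + SHORE_BP),
            ],
            ignore_index=True,
        )
        shelves = pd.concat(
            [
                isl.assign(start=isl["start"] - SHORE_BP - SHELF_BP, end=isl["start"] - SHORE_BP),
                isl.assign(start=isl["end"] + SHORE_BP, end=isl["end"] + SHORE_BP + SHELF_BP),
            ],
            ignore_index=True,
        )
        self.island_tracks = {
            "island": isl,
            "shore": _clip_to_bounds(_merge_intervals(shores), self.chrom_sizes, "shore"),
            "shelf": _clip_to_bounds(_merge_intervals(shelves), self.chrom_sizes, "shelf"),
        }

    def _build_feature_tracks(self):
        g = self.genes
        tracks: dict[str, list] = {k: [] for k in FEATURE_PRECEDENCE}
        for row in g.itertuples(index=False):
            chrom, start, end, strand = row.chrom, int(row.start), int(row.end), row.strand
            if strand == "+":
                tss = start
                tracks["promoter"].append((chrom, tss - PROMOTER_BP, tss))
                tracks["up5kb"].append((chrom, tss - PROMOTER_BP - UP5KB_BP, tss - PROMOTER_BP))
            else:
                tss = end
                tracks["promoter"].append((chrom, tss, tss + PROMOTER_BP))
                tracks["up5kb"].append((chrom, tss + PROMOTER_BP, tss + PROMOTER_BP + UP5KB_BP))
            # simple gene body model: terminal UTRs flanking alternating
            # exon/intron segments
            utr = min(200, (end - start) // 4)
            if strand == "+":
                tracks["utr5"].append((chrom, start, start + utr))
                tracks["utr3"].append((chrom, end - utr, end))
            else:
                tracks["utr5"].append((chrom, end - utr, end))
                tracks["utr3"].append((chrom, start, start + utr))
            body_start, body_end = start + utr, end - utr
            seg = 1000
            pos, k = body_start, 0
            while pos < body_end:
                stop = min(pos + seg, body_end)
                tracks["exon" if k % 2 == 0 else "intron"].append((chrom, pos, stop))
                pos, k = stop, k + 1
        self.feature_tracks = {}
        for label, rows in tracks.items():
            df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
            df = _clip_to_bounds(df, self.chrom_sizes, label)
            self.feature_tracks[label] = _merge_intervals(df)

    # -- queries ----------------------------------------------------------
    def island_label(self, chroms: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """island > shore > shelf > open_sea, per site."""
        chroms = np.asarray(chroms)
        pos = np.asarray(pos)
        label = np.full(len(pos), "open_sea", dtype=object)
        unassigned = np.ones(len(pos), dtype=bool)
        for name in ISLAND_PRECEDENCE:
            hit = _membership(self.island_tracks[name], chroms, pos) & unassigned
            label[hit] = name
            unassigned &= ~hit
        return label

    def feature_label(self, chroms: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """promoter > 5'UTR > exon > intron > 3'UTR > up5kb > intergenic."""
        chroms = np.asarray(chroms)
        pos = np.asarray(pos)
        label = np.full(len(pos), "intergenic", dtype=object)
        unassigned = np.ones(len(pos), dtype=bool)
        for name in FEATURE_PRECEDENCE:
            hit = _membership(self.feature_tracks[name], chroms, pos) & unassigned
            label[hit] = name
            unassigned &= ~hit
        return label

    def tss_anchors(self) -> pd.DataFrame:
        """Stranded TSS positions for profile plots."""
        g = self.genes
        tss = np.where(g["strand"] == "+", g["start"], g["end"] - 1)
        return pd.DataFrame({"chrom": g["chrom"], "pos": tss.astype(np.int64),
                             "strand": g["strand"]})

    # -- I/O ---------------------------------------------------------------
    def write_bed(self, directory) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = {}
        for name, df in {**self.island_tracks, **self.feature_tracks}.items():
            path = directory / f"{name}.bed"
            df.to_csv(path, sep="\t", header=False, index=False)
            written[name] = path
        genes = self.genes.copy()
        genes["name"] = [f"gene{i}" for i in range(len(genes))]
        genes["score"] = 0
        genes[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
            directory / "genes.bed", sep="\t", header=False, index=False
        )
        written["genes"] = directory / "genes.bed"
        return written
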