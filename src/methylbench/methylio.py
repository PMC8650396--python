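"""Per-CpG methylation call sets in the 6-column bedGraph dialect.

Records carry chrom, 0-based half-open interval, strand, context and the
methylated/unmethylated observation counts. Counts are the source of truth;
the percent column of the on-disk format is presentation-only and is
recomputed on write.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import BedGraphParseError, ValidationError

#: canonical column order of the in-memory record table
COLUMNS = ["chrom", "start", "end", "strand", "context", "n_meth", "n_unmeth"]

VALID_STRANDS = {"+", "-", "merged", "."}
VALID_CONTEXTS = {"CpG", "CHG", "CHH"}


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass
class MethylCallSet:
    """A sorted table of per-cytosine (or per-CpG-dinucleotide) call records.

    Parameters
    ----------
    records : pandas.DataFrame
        Columns ``chrom, start, end, strand, context, n_meth, n_unmeth``.
        Sorted by (chrom, start); unique on (chrom, start, strand).
    metadata : dict
        Free-form sample metadata; conventional keys are ``assay``, ``lab``,
        ``genome``, ``replicate``, ``build`` and ``context_filter``.
    """

    records: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        df = self.records
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"missing record columns: {missing}")
        df = df.loc[:, COLUMNS].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["n_meth"] = df["n_meth"].astype(np.int64)
        df["n_unmeth"] = df["n_unmeth"].astype(np.int64)
        if (df["n_meth"] < 0).any() or (df["n_unmeth"] < 0).any():
            raise ValidationError("negative counts")
        df = df.sort_values(["chrom", "start", "strand"], kind="mergesort")
        df = df.reset_index(drop=True)
        if df.duplicated(["chrom", "start", "strand"]).any():
            raise ValidationError("duplicate (chrom, start, strand) keys")
        self.records = df

    # -- derived views ----------------------------------------------------
    @property
    def coverage(self) -> np.ndarray:
        return (self.records["n_meth"] + self.records["n_unmeth"]).to_numpy()

    @property
    def beta(self) -> np.ndarray:
        cov = self.coverage.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, self.records["n_meth"].to_numpy() / cov, np.nan)

    @property
    def is_merged(self) -> bool:
        """True if every record spans a dinucleotide [s, s+2)."""
        if len(self.records) == 0:
            return True
        return bool((self.records["end"] - self.records["start"] == 2).all())

    def __len__(self) -> int:
        return len(self.records)

    def site_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.records[["chrom", "start"]])

    def with_metadata(self, **kw) -> "MethylCallSet":
        return MethylCallSet(self.records, {**self.metadata, **kw})


def read_bedgraph(path, metadata: dict | None = None, context: str = "CpG") -> MethylCallSet:
    """Parse a 6-column methylation bedGraph.

    Columns: chrom, start, end, percent-methylation, n_meth, n_unmeth.
    The percent column is ignored (recomputed from counts). An optional
    ``track`` header line is tolerated. Strand is inferred from the span:
    [s, s+2) records are ``merged`` dinucleotides, [s, s+1) records are
    single cytosines with unknown strand (``.``).
    """
    chroms, starts, ends, meths, unmeths = [], [], [], [], []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if lineno == 1 and (line.startswith("track") or line.startswith("#")):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise BedGraphParseError(
                    f"expected 6 tab-separated columns, got {len(fields)}", lineno
                )
            try:
                start, end = int(fields[1]), int(fields[2])
                n_meth, n_unmeth = int(fields[4]), int(fields[5])
            except ValueError as exc:
                raise BedGraphParseError(str(exc), lineno) from None
            if n_meth < 0 or n_unmeth < 0:
                raise ValidationError(f"line {lineno}: negative counts")
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
            meths.append(n_meth)
            unmeths.append(n_unmeth)
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    strand = np.where(ends - starts == 2, "merged", ".")
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": ends,
            "strand": strand,
            "context": context,
            "n_meth": np.asarray(meths, dtype=np.int64),
            "n_unmeth": np.asarray(unmeths, dtype=np.int64),
        }
    )
    return MethylCallSet(df, dict(metadata or {}))


def write_bedgraph(callset: MethylCallSet, path) -> None:
    """Write the 6-column dialect; column 4 is beta*100 rounded half-up."""
    df = callset.records
    cov = (df["n_meth"] + df["n_unmeth"]).to_numpy().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(cov > 0, df["n_meth"].to_numpy() / cov, 0.0)
    pct = np.floor(beta * 100.0 + 0.5).astype(np.int64)
    with _open_text(path, "wt") as fh:
        for chrom, start, end, p, m, u in zip(
            df["chrom"], df["start"], df["end"], pct, df["n_meth"], df["n_unmeth"]
        ):
            fh.write(f"{chrom}\t{start}\t{end}\t{p}\t{m}\t{u}\n")


def merge_context(callset: MethylCallSet) -> MethylCallSet:
    """Combine strand-symmetric CpG cytosines into dinucleotide records.

    A + strand C at position s pairs with the − strand C at s+1; the merged
    record spans [s, s+2) with summed counts. Lone-strand sites pass through
    as [s, s+2) anchored at the + strand C position (a lone − strand C at s
    anchors at s−1). Records with unknown strand (``.``) are paired by
    adjacency: a record at s+1 immediately following one at s is treated as
    the − strand partner. Already-merged records are returned unchanged.
    """
    df = callset.records
    if len(df) == 0 or callset.is_merged:
        return MethylCallSet(df.copy(), dict(callset.metadata))

    merged_rows = df[df["strand"] == "merged"]
    single = df[df["strand"] != "merged"]

    chrom = single["chrom"].to_numpy()
    start = single["start"].to_numpy()
    strand = single["strand"].to_numpy()
    n_meth = single["n_meth"].to_numpy()
    n_unmeth = single["n_unmeth"].to_numpy()
    context = single["context"].to_numpy()

    n = len(single)
    # anchor position of the dinucleotide each record belongs to
    anchor = start.copy()
    if n:
        # explicit − strand C at s always anchors at the + strand C position s−1
        is_minus = (strand == "-").copy()
        # adjacency pairing for unknown strands: a '.' record at the base
        # directly after an anchor record plays the − strand role; scan so a
        # run of adjacent records does not chain
        unknown = strand == "."
        prev_same = np.zeros(n, dtype=bool)
        prev_same[1:] = (chrom[1:] == chrom[:-1]) & (start[1:] == start[:-1] + 1)
        for i in np.flatnonzero(unknown & prev_same):
            if not is_minus[i - 1]:
                is_minus[i] = True
        anchor[is_minus] -= 1

    key = pd.DataFrame(
        {"chrom": chrom, "start": anchor, "context": context,
         "n_meth": n_meth, "n_unmeth": n_unmeth}
    )
    agg = key.groupby(["chrom", "start"], as_index=False, sort=False).agg(
        context=("context", "first"), n_meth=("n_meth", "sum"), n_unmeth=("n_unmeth", "sum")
    )
    agg["end"] = agg["start"] + 2
    agg["strand"] = "merged"
    out = pd.concat([merged_rows[COLUMNS], agg[COLUMNS]], ignore_index=True)
    return MethylCallSet(out, dict(callset.metadata))


def merge_replicates(
    callsets: Sequence[MethylCallSet], allow_lab_mismatch: bool = False
) -> MethylCallSet:
    """Union of sites with per-site summed counts across replicates."""
    if not callsets:
        raise ValidationError("no call sets to merge")
    states = {cs.is_merged for cs in callsets}
    if len(states) > 1:
        raise ValidationError("cannot merge mixed merged/unmerged contexts")
    for key in ("assay", "genome"):
        vals = {cs.metadata.get(key) for cs in callsets}
        if len(vals) > 1:
            raise ValidationError(f"replicates disagree on {key}: {vals}")
    if not allow_lab_mismatch:
        labs = {cs.metadata.get("lab") for cs in callsets}
        if len(labs) > 1:
            raise ValidationError(
                f"replicates come from different labs {labs}; "
                "pass allow_lab_mismatch=True to combine"
            )
    big = pd.concat([cs.records for cs in callsets], ignore_index=True)
    agg = big.groupby(["chrom", "start", "strand"], as_index=False, sort=False).agg(
        end=("end", "first"), context=("context", "first"),
        n_meth=("n_meth", "sum"), n_unmeth=("n_unmeth", "sum")
    )
    meta = dict(callsets[0].metadata)
    meta["replicate"] = "merged"
    meta["constituents"] = [cs.metadata.get("replicate") for cs in callsets]
    return MethylCallSet(agg[COLUMNS], meta)


def restrict(
    callset: MethylCallSet,
    regions: Iterable[tuple[str, int, int]] | None = None,
    chrom: str | None = None,
) -> MethylCallSet:
    """Keep records whose start lies inside a half-open region (or chromosome)."""
    df = callset.records
    if chrom is not None:
        if chrom not in set(df["chrom"]):
            warnings.warn(f"chromosome {chrom!r} not present in call set")
        out = df[df["chrom"] == chrom]
        return MethylCallSet(out.copy(), dict(callset.metadata))
    regions = list(regions or [])
    if not regions:
        return MethylCallSet(df.iloc[0:0].copy(), dict(callset.metadata))
    keep = np.zeros(len(df), dtype=bool)
    chroms = df["chrom"].to_numpy()
    starts = df["start"].to_numpy()
    known = set(chroms)
    for rchrom, rstart, rend in regions:
        if rend < rstart:
            raise ValidationError(f"invalid region {rchrom}:{rstart}-{rend}")
        if rchrom not in known:
            warnings.warn(f"region chromosome {rchrom!r} not present in call set")
            continue
        keep |= (chroms == rchrom) & (starts >= rstart) & (starts < rend)
    return MethylCallSet(df[keep].copy(), dict(callset.metadata))


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED6 intervals into a DataFrame (chrom, start, end[, name, score, strand])."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            rows.append(parts[:6])
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    width = max(len(r) for r in rows)
    df = pd.DataFrame(rows, columns=names[:width])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df.columns]
    df.loc[:, cols].to_csv(path, sep="\t", header=False, index=False)
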