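"""Coverage, efficiency, conversion and annotation-profile metrics.

Conventions: mean CpG coverage is computed over covered sites (the call-set
format has no zero-coverage rows), while capture and >=k-fold fractions are
computed over the full reference CpG set with uncovered reference sites
counting as 0x.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import AnnotationSet
from .errors import ValidationError
from .methylio import MethylCallSet


@dataclass
class CoverageSummary:
    mean_coverage: float
    ecdf: pd.DataFrame  # columns: coverage, cumulative_fraction
    fraction_at_least: dict[int, float]  # k -> fraction of reference CpGs >= k x
    capture_fraction: float  # reference CpGs covered >= 1x / total
    n_reference: int
    n_covered: int


def _reference_frame(reference_cpg_set) -> pd.DataFrame:
    if isinstance(reference_cpg_set, pd.DataFrame):
        ref = reference_cpg_set[["chrom", "pos"]]
    else:
        ref = pd.DataFrame(list(reference_cpg_set), columns=["chrom", "pos"])
    if len(ref) == 0:
        raise ValidationError("empty reference CpG set")
    return ref


def coverage_summary(
    callset: MethylCallSet, reference_cpg_set, k_list=(1, 5, 10, 20)
) -> CoverageSummary:
    """Summarize per-CpG coverage against a reference CpG position set."""
    ref = _reference_frame(reference_cpg_set)
    obs = callset.records[["chrom", "start"]].copy()
    obs["coverage"] = callset.coverage
    merged = ref.merge(
        obs.rename(columns={"start": "pos"}), on=["chrom", "pos"], how="left"
    )
    ref_cov = merged["coverage"].fillna(0).to_numpy()

    cov = callset.coverage
    covered = cov[cov > 0]
    mean_cov = float(covered.mean()) if covered.size else 0.0

    values, counts = np.unique(covered, return_counts=True)
    ecdf = pd.DataFrame(
        {"coverage": values, "cumulative_fraction": np.cumsum(counts) / max(1, covered.size)}
    )
    frac = {int(k): float((ref_cov >= k).mean()) for k in k_list}
    return CoverageSummary(
        mean_coverage=mean_cov,
        ecdf=ecdf,
        fraction_at_least=frac,
        capture_fraction=float((ref_cov >= 1).mean()),
        n_reference=len(ref),
        n_covered=int(covered.size),
    )


def reads_for_target(observed_pairs: int, observed_mean_cov: float, target_cov: float) -> int:
    """Read pairs needed for a target mean CpG coverage, by linear scaling."""
    if observed_pairs <= 0 or observed_mean_cov <= 0 or target_cov <= 0:
        raise ValidationError("inputs must be positive")
    return int(math.ceil(observed_pairs * target_cov / observed_mean_cov))


def usable_bases(bases_in_retained_reads: int, total_bases_sequenced: int) -> float:
    """Fraction of sequenced bases that informed methylation calls."""
    if bases_in_retained_reads < 0 or total_bases_sequenced <= 0:
        raise ValidationError("base counts must be non-negative (total > 0)")
    if bases_in_retained_reads > total_bases_sequenced:
        raise ValidationError("retained bases exceed total bases")
    return bases_in_retained_reads / total_bases_sequenced


def conversion_report(
    callset: MethylCallSet, spike_in_names=("lambda", "pUC19")
) -> dict:
    """Pooled apparent methylation per spike-in contig and per context.

    The pooled estimate is sum(n_meth)/sum(coverage) (the binomial MLE).
    Conversion efficiency of an unmethylated control is 1 − apparent
    methylation. Absent contigs are reported as None.
    """
    df = callset.records
    cov = df["n_meth"] + df["n_unmeth"]

    def pooled(mask) -> float | None:
        total = int(cov[mask].sum())
        if total == 0:
            return None
        return float(df.loc[mask, "n_meth"].sum() / total)

    report = {"contigs": {}, "contexts": {}}
    for name in spike_in_names:
        apparent = pooled(df["chrom"] == name)
        entry = {"apparent_methylation": apparent}
        if apparent is not None:
            entry["conversion_efficiency"] = 1.0 - apparent
        report["contigs"][name] = entry
    for ctx in sorted(df["context"].unique()):
        report["contexts"][ctx] = {"apparent_methylation": pooled(df["context"] == ctx)}
    return report


def nucleotide_enrichment(covered_intervals, fasta_path, pseudofrequency: float = 1e-9):
    """log2(covered frequency / genome frequency) per mono- and dinucleotide.

    Dinucleotides are counted in overlapping windows on the + strand only.
    Intervals outside contig bounds are clipped with a warning.
    """
    from pyfaidx import Fasta

    fasta = Fasta(str(fasta_path))
    mono_genome: dict[str, int] = {}
    di_genome: dict[str, int] = {}
    for name in fasta.keys():
        seq = str(fasta[name][:]).upper()
        _count_into(seq, mono_genome, di_genome)

    mono_cov: dict[str, int] = {}
    di_cov: dict[str, int] = {}
    if isinstance(covered_intervals, pd.DataFrame):
        covered_intervals = covered_intervals[["chrom", "start", "end"]].itertuples(index=False)
    for chrom, start, end in covered_intervals:
        if chrom not in fasta:
            warnings.warn(f"interval chromosome {chrom!r} not in FASTA; skipped")
            continue
        length = len(fasta[chrom])
        if start < 0 or end > length:
            warnings.warn(f"interval {chrom}:{start}-{end} clipped to contig bounds")
        s, e = max(0, start), min(length, end)
        if e <= s:
            continue
        seq = str(fasta[chrom][s:e]).upper()
        _count_into(seq, mono_cov, di_cov)

    def enrich(cov_counts: dict, genome_counts: dict, keys) -> dict:
        tot_cov = max(1, sum(cov_counts.get(k, 0) for k in keys))
        tot_gen = max(1, sum(genome_counts.get(k, 0) for k in keys))
        out = {}
        for k in keys:
            f_cov = cov_counts.get(k, 0) / tot_cov + pseudofrequency
            f_gen = genome_counts.get(k, 0) / tot_gen + pseudofrequency
            out[k] = math.log2(f_cov / f_gen)
        return out

    bases = list("ACGT")
    dinucs = [a + b for a in bases for b in bases]
    return {
        "mono": enrich(mono_cov, mono_genome, bases),
        "di": enrich(di_cov, di_genome, dinucs),
    }


def _count_into(seq: str, mono: dict, di: dict) -> None:
    arr = np.frombuffer(seq.encode(), dtype="S1")
    vals, counts = np.unique(arr, return_counts=True)
    for v, c in zip(vals, counts):
        b = v.decode()
        if b in "ACGT":
            mono[b] = mono.get(b, 0) + int(c)
    if len(seq) >= 2:
        first, second = arr[:-1], arr[1:]
        for a in b"ACGT":
            for b2 in b"ACGT":
                c = int(np.count_nonzero((first == bytes([a])) & (second == bytes([b2]))))
                if c:
                    key = chr(a) + chr(b2)
                    di[key] = di.get(key, 0) + c


def annotation_assign(callset: MethylCallSet, annotations: AnnotationSet) -> pd.DataFrame:
    """Per-site feature and island labels (single label each, by precedence)."""
    chroms = callset.records["chrom"].to_numpy()
    pos = callset.records["start"].to_numpy()
    return pd.DataFrame(
        {
            "chrom": chroms,
            "start": pos,
            "feature": annotations.feature_label(chroms, pos),
            "island": annotations.island_label(chroms, pos),
        }
    )


def region_profile(
    callset: MethylCallSet,
    anchors: pd.DataFrame,
    window: int = 2000,
    bin_width: int = 100,
    value: str = "coverage",
) -> pd.DataFrame:
    """Mean coverage or beta as a function of distance from stranded anchors.

    Minus-strand anchors are flipped so that positive offsets always point
    downstream of the anchor. Returns columns (offset, mean, n).
    """
    if value not in ("coverage", "beta"):
        raise ValidationError("value must be 'coverage' or 'beta'")
    df = callset.records
    vals = callset.coverage.astype(float) if value == "coverage" else callset.beta

    offsets, collected = [], []
    for chrom, grp in anchors.groupby("chrom", sort=False):
        sel = df["chrom"].to_numpy() == chrom
        if not sel.any():
            continue
        spos = df["start"].to_numpy()[sel]
        svals = vals[sel]
        order = np.argsort(spos)
        spos, svals = spos[order], svals[order]
        for anchor_pos, strand in zip(grp["pos"].to_numpy(), grp["strand"].to_numpy()):
            lo = np.searchsorted(spos, anchor_pos - window, side="left")
            hi = np.searchsorted(spos, anchor_pos + window, side="right")
            if hi <= lo:
                continue
            off = spos[lo:hi] - anchor_pos
            if strand == "-":
                off = -off
            offsets.append(off)
            collected.append(svals[lo:hi])
    if not offsets:
        warnings.warn("no sites found in any anchor window")
        return pd.DataFrame(columns=["offset", "mean", "n"])
    off = np.concatenate(offsets)
    val = np.concatenate(collected)
    bins = (np.floor(off / bin_width) * bin_width).astype(int)
    out = (
        pd.DataFrame({"offset": bins, "value": val})
        .groupby("offset")["value"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"count": "n"})
    )
    return out.rename(columns={"value": "mean"})


def metagene_summary(callset: MethylCallSet, annotations: AnnotationSet) -> pd.DataFrame:
    """Unweighted mean beta per feature class; empty classes reported as NaN."""
    labels = annotation_assign(callset, annotations)
    labels["beta"] = callset.beta
    classes = ["promoter", "utr5", "exon", "intron", "utr3", "up5kb", "intergenic"]
    means = labels.groupby("feature")["beta"].agg(["mean", "count"])
    means = means.reindex(classes)
    means["count"] = means["count"].fillna(0).astype(int)
    return means.reset_index().rename(columns={"feature": "class", "mean": "mean_beta", "count": "n"})
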