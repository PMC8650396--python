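"""Replicate reproducibility and cross-assay concordance scoring."""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import AnnotationSet
from .errors import ValidationError
from .methylio import MethylCallSet


def _intersect_frames(callsets, columns=("n_meth", "n_unmeth")) -> list[pd.DataFrame]:
    """Restrict all call sets to their common (chrom, start) sites, aligned."""
    frames = []
    for cs in callsets:
        df = cs.records.set_index(["chrom", "start"])[list(columns)]
        frames.append(df)
    common = reduce(lambda a, b: a.intersection(b), (f.index for f in frames))
    common = common.sort_values()
    return [f.loc[common] for f in frames]


def replicate_sd(callsets, bin_edges=None) -> pd.DataFrame:
    """Per-site SD of replicate betas vs mean coverage, optionally binned.

    Only sites present in every replicate are used. Returns one row per site
    (mean_coverage, sd) or, when ``bin_edges`` is given, per coverage bin
    (bin_left, mean_sd, rms_sd, n). The rms column is sqrt(mean variance),
    the summary the iid expectation curve predicts without small-K bias.
    """
    if len(callsets) < 2:
        raise ValidationError("need at least 2 replicates")
    frames = _intersect_frames(callsets)
    cov = np.stack([(f["n_meth"] + f["n_unmeth"]).to_numpy(float) for f in frames])
    beta = np.stack([(f["n_meth"] / (f["n_meth"] + f["n_unmeth"])).to_numpy(float) for f in frames])
    per_site = pd.DataFrame(
        {
            "mean_coverage": cov.mean(axis=0),
            "sd": beta.std(axis=0, ddof=1),
        },
        index=frames[0].index,
    )
    if bin_edges is None:
        return per_site
    binned = per_site.copy()
    binned["bin"] = pd.cut(binned["mean_coverage"], bin_edges, right=False)
    out = (
        binned.groupby("bin", observed=True)
        .agg(
            mean_sd=("sd", "mean"),
            rms_sd=("sd", lambda s: float(np.sqrt(np.mean(s**2)))),
            n=("sd", "size"),
        )
        .reset_index()
    )
    out["bin_left"] = out["bin"].map(lambda iv: iv.left).astype(float)
    return out


@dataclass
class ExpectedSdCurve:
    """SD expected between iid replicate betas of a common proportion p."""

    coverage_grid: np.ndarray
    expected_sd: np.ndarray
    mean_p_variance: float  # mean over sites of p(1-p)

    def at(self, coverage: float) -> float:
        return float(np.sqrt(self.mean_p_variance / coverage))


def expected_sd_curve(pooled_p_per_site, coverage_grid) -> ExpectedSdCurve:
    """Expected replicate SD at coverage c: sqrt(mean_sites[p(1−p)] / c)."""
    p = np.asarray(pooled_p_per_site, dtype=float)
    if p.size == 0:
        raise ValidationError("empty site set")
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("pooled proportions must lie in [0, 1]")
    grid = np.asarray(coverage_grid, dtype=float)
    if (grid <= 0).any():
        raise ValidationError("coverage grid must be positive")
    mean_var = float(np.mean(p * (1.0 - p)))
    return ExpectedSdCurve(grid, np.sqrt(mean_var / grid), mean_var)


def _named(callsets) -> dict[str, MethylCallSet]:
    if isinstance(callsets, dict):
        return callsets
    out = {}
    for i, cs in enumerate(callsets):
        name = cs.metadata.get("assay") or f"set{i}"
        if name in out:
            name = f"{name}_{i}"
        out[name] = cs
    return out


def beta_correlation_matrix(
    callsets, stratum: str | tuple = "all", stratum_on: str = "mean"
) -> pd.DataFrame:
    """Pairwise Pearson correlation of betas over the common-site intersection.

    ``stratum`` may be "all" or a (lo, hi) beta interval, e.g. (0.2, 0.8).
    Stratum membership is judged per pair on the mean of the two call sets'
    betas (``stratum_on="mean"``) or on one named call set's beta.
    """
    named = _named(callsets)
    if len(named) < 2:
        raise ValidationError("need at least 2 call sets")
    names = list(named)
    frames = _intersect_frames(list(named.values()))
    betas = {
        n: (f["n_meth"] / (f["n_meth"] + f["n_unmeth"])).to_numpy(float)
        for n, f in zip(names, frames)
    }
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            x, y = betas[a], betas[b]
            if stratum == "all":
                sel = np.ones(len(x), dtype=bool)
            else:
                lo, hi = stratum
                if stratum_on == "mean":
                    ref = (x + y) / 2.0
                else:
                    ref = betas[stratum_on]
                sel = (ref >= lo) & (ref <= hi)
            if sel.sum() < 3 or np.std(x[sel]) == 0 or np.std(y[sel]) == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(x[sel], y[sel])[0, 1])
            mat.loc[a, b] = mat.loc[b, a] = r
    return mat


def coverage_correlation(callsets, method: str = "spearman") -> pd.DataFrame:
    """Pairwise rank correlation of per-site coverages on common sites."""
    named = _named(callsets)
    if len(named) < 2:
        raise ValidationError("need at least 2 call sets")
    names = list(named)
    frames = _intersect_frames(list(named.values()))
    covs = {n: (f["n_meth"] + f["n_unmeth"]).to_numpy(float) for n, f in zip(names, frames)}
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            if len(covs[a]) < 3:
                rho = np.nan
            elif method == "spearman":
                rho = float(stats.spearmanr(covs[a], covs[b]).statistic)
            else:
                rho = float(np.corrcoef(covs[a], covs[b])[0, 1])
            mat.loc[a, b] = mat.loc[b, a] = rho
    return mat


@dataclass
class SiteIntersections:
    """Exact-subset intersection counts plus per-assay unique covered/missed sets."""

    pattern_counts: dict[tuple, int]  # subset of assays (sorted tuple) -> count
    unique_covered: dict[str, pd.MultiIndex]
    unique_missed: dict[str, pd.MultiIndex]
    union_size: int

    def to_json_dict(self) -> dict:
        return {
            "union_size": self.union_size,
            "patterns": {"+".join(k): v for k, v in self.pattern_counts.items()},
            "unique_covered": {k: len(v) for k, v in self.unique_covered.items()},
            "unique_missed": {k: len(v) for k, v in self.unique_missed.items()},
        }


def site_intersections(callsets, min_cov: int = 1) -> SiteIntersections:
    """Assign every site to the exact subset of assays covering it at >=min_cov."""
    named = _named(callsets)
    if len(named) < 2:
        raise ValidationError("need at least 2 call sets")
    names = list(named)
    members = {}
    for n, cs in named.items():
        df = cs.records
        ok = (df["n_meth"] + df["n_unmeth"]) >= min_cov
        members[n] = pd.MultiIndex.from_frame(df.loc[ok, ["chrom", "start"]])
    union = reduce(lambda a, b: a.union(b), members.values()).sort_values()
    flags = np.zeros((len(union), len(names)), dtype=bool)
    for j, n in enumerate(names):
        flags[:, j] = union.isin(members[n])
    pattern_counts: dict[tuple, int] = {}
    codes = flags.dot(1 << np.arange(len(names)))
    for code, count in zip(*np.unique(codes, return_counts=True)):
        subset = tuple(names[j] for j in range(len(names)) if code & (1 << j))
        pattern_counts[subset] = int(count)
    n_present = flags.sum(axis=1)
    unique_cov = {}
    unique_missed = {}
    for j, n in enumerate(names):
        unique_cov[n] = union[(n_present == 1) & flags[:, j]]
        unique_missed[n] = union[(n_present == len(names) - 1) & ~flags[:, j]]
    return SiteIntersections(pattern_counts, unique_cov, unique_missed, len(union))


def unique_site_annotation(
    unique_sets: dict[str, pd.MultiIndex], annotations: AnnotationSet
) -> pd.DataFrame:
    """Feature-label counts per assay for its unique covered/missed sites."""
    rows = []
    for assay, sites in unique_sets.items():
        if len(sites) == 0:
            rows.append({"assay": assay})
            continue
        chroms = sites.get_level_values(0).to_numpy()
        pos = sites.get_level_values(1).to_numpy()
        labels = annotations.feature_label(chroms, pos)
        counts = pd.Series(labels).value_counts().to_dict()
        rows.append({"assay": assay, **counts})
    out = pd.DataFrame(rows).set_index("assay").fillna(0).astype(int)
    return out
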