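"""Microarray beta-matrix evaluation: per-site variance partition and the
SNP-probe-derived low-variance site filter.

Variance components for crossed random factors (e.g. cell line + lab) are
estimated per site by a method-of-moments on fixed-effect projection
quadratic forms (Henderson's method III). Because every site shares the one
sample design, the quadratic-form matrices and the coefficient system are
precomputed once and the per-site estimates reduce to matrix products, which
makes the estimator deterministic, unbiased for any (possibly unbalanced)
design, and fast for full-array matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class BetaMatrix:
    """Sites x samples matrix of array betas with site and sample metadata.

    ``values``: DataFrame indexed by probe id, columns = sample ids.
    ``site_meta``: indexed like ``values``; must carry ``is_snp_probe``.
    ``sample_meta``: indexed by sample id; must carry ``cell_line``, ``lab``,
    ``replicate`` (and optionally ``assay``).
    """

    values: pd.DataFrame
    site_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self):
        if not self.values.index.equals(self.site_meta.index):
            raise ValidationError("values and site_meta must share the probe index")
        if list(self.values.columns) != list(self.sample_meta.index):
            raise ValidationError("values columns must match sample_meta index")
        if "is_snp_probe" not in self.site_meta.columns:
            raise ValidationError("site_meta needs an is_snp_probe column")
        for col in ("cell_line", "lab", "replicate"):
            if col not in self.sample_meta.columns:
                raise ValidationError(f"sample_meta needs a {col} column")
        vals = self.values.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and ((finite < -1e-9).any() or (finite > 1 + 1e-9).any()):
            raise ValidationError("beta values must lie in [0, 1] (or be missing)")

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def snp_probes(self) -> pd.DataFrame:
        return self.values.loc[self.site_meta["is_snp_probe"].to_numpy(bool)]

    def autosomal_probes(self) -> pd.DataFrame:
        return self.values.loc[~self.site_meta["is_snp_probe"].to_numpy(bool)]

    # -- I/O ---------------------------------------------------------------
    def write_csv(self, values_path, samples_path, sites_path=None) -> None:
        self.values.to_csv(values_path)
        self.sample_meta.to_csv(samples_path)
        if sites_path is not None:
            self.site_meta.to_csv(sites_path)

    @classmethod
    def read_csv(cls, values_path, samples_path, sites_path=None) -> "BetaMatrix":
        values = pd.read_csv(values_path, index_col=0)
        samples = pd.read_csv(samples_path, index_col=0)
        if sites_path is not None:
            sites = pd.read_csv(sites_path, index_col=0)
            if "is_snp_probe" in sites.columns:
                sites["is_snp_probe"] = sites["is_snp_probe"].astype(bool)
        else:
            sites = pd.DataFrame(
                {"is_snp_probe": values.index.str.startswith("rs")}, index=values.index
            )
        return cls(values, sites, samples)


@dataclass
class VariancePartition:
    """Per-site variance-explained fractions, one column per factor + residual."""

    fractions: pd.DataFrame  # columns: VE_<factor>..., VE_residual
    components: pd.DataFrame  # raw variance-component estimates (clamped at 0)
    factors: tuple

    def median_ve(self, factor: str) -> float:
        return float(self.fractions[f"VE_{factor}"].median())


def _dummies(labels: pd.Series) -> np.ndarray:
    return pd.get_dummies(labels).to_numpy(dtype=float)


def _projection(x: np.ndarray) -> np.ndarray:
    # column space projector via pinv (handles rank deficiency from dummies)
    return x @ np.linalg.pinv(x)


def variance_partition(matrix: BetaMatrix, factors=("cell_line", "lab")) -> VariancePartition:
    """Per-site crossed random-effects decomposition of beta variance.

    For each factor the quadratic form Q_f = P_full − P_without-f isolates the
    factor's contribution after the other factors; expectations of y'Qy are
    solved exactly for the variance components, negatives are clamped to 0,
    and fractions are components over their sum. Sites with missing values
    are estimated on their complete cases.
    """
    meta = matrix.sample_meta
    for f in factors:
        if f not in meta.columns:
            raise ValidationError(f"sample_meta has no factor column {f!r}")
        if meta[f].nunique() < 2:
            raise ValidationError(f"factor {f!r} needs >= 2 levels")
    for i, f in enumerate(factors):
        for g in factors[i + 1 :]:
            if meta.groupby(f)[g].transform("first").eq(meta[g]).all() and \
               meta.groupby(g)[f].transform("first").eq(meta[f]).all():
                raise ValidationError(f"factors {f!r} and {g!r} are confounded")

    values = matrix.values.to_numpy(dtype=float)
    complete = np.isfinite(values).all(axis=1)

    comp_rows = np.full((matrix.n_sites, len(factors) + 1), np.nan)
    if complete.any():
        comp_rows[complete] = _vp_components(values[complete], meta, factors)
    for i in np.flatnonzero(~complete):
        obs = np.isfinite(values[i])
        if obs.sum() < len(factors) + 2:
            continue
        sub_meta = meta.loc[obs]
        if any(sub_meta[f].nunique() < 2 for f in factors):
            continue
        comp_rows[i] = _vp_components(values[i][obs][None, :], sub_meta, factors)[0]

    comp = pd.DataFrame(
        comp_rows, index=matrix.values.index,
        columns=[f"var_{f}" for f in factors] + ["var_residual"],
    )
    total = comp.sum(axis=1)
    frac = comp.div(total.where(total > 0), axis=0)
    frac.loc[total == 0] = 0.0
    if (total == 0).any():
        frac.loc[total == 0, "var_residual"] = 1.0
    frac.columns = [f"VE_{f}" for f in factors] + ["VE_residual"]
    return VariancePartition(fractions=frac, components=comp, factors=tuple(factors))


def _vp_components(values: np.ndarray, meta: pd.DataFrame, factors) -> np.ndarray:
    """Henderson-III estimates for a (n_sites, n_samples) block, shared design."""
    n = values.shape[1]
    z = {f: _dummies(meta[f]) for f in factors}
    ones = np.ones((n, 1))
    x_full = np.hstack([ones] + [z[f] for f in factors])
    p_full = _projection(x_full)
    m_e = np.eye(n) - p_full

    quads = []
    for f in factors:
        x_wo = np.hstack([ones] + [z[g] for g in factors if g != f])
        quads.append(p_full - _projection(x_wo))
    quads.append(m_e)

    k = len(factors) + 1
    coef = np.zeros((k, k))
    gram = [z[f] @ z[f].T for f in factors] + [np.eye(n)]
    for a, q in enumerate(quads):
        for b, g in enumerate(gram):
            coef[a, b] = np.trace(q @ g)
    if abs(np.linalg.det(coef)) < 1e-10:
        raise ValidationError("variance-component system is singular (confounded design)")

    # u[a, site] = y' Q_a y, vectorized over sites
    u = np.stack([np.einsum("sn,nm,sm->s", values, q, values) for q in quads])
    comps = np.linalg.solve(coef, u)  # (k, n_sites)
    return np.maximum(comps.T, 0.0)


def pipeline_rank(matrices: dict[str, BetaMatrix], factors=("cell_line", "lab")):
    """Rank normalization pipelines by median VE of the first factor."""
    if not matrices:
        raise ValidationError("no matrices to rank")
    primary = factors[0]
    rows, dists = [], {}
    for name, mat in matrices.items():
        vp = variance_partition(mat, factors=factors)
        ve = vp.fractions[f"VE_{primary}"].dropna()
        rows.append((name, float(ve.median())))
        dists[name] = ve
    table = pd.DataFrame(rows, columns=["pipeline", f"median_VE_{primary}"])
    table = table.sort_values(f"median_VE_{primary}", ascending=False, kind="mergesort")
    table["rank"] = np.arange(1, len(table) + 1)
    return table.reset_index(drop=True), dists


# ---------------------------------------------------------------------------
# SNP-probe technical-noise filter
# ---------------------------------------------------------------------------

def snp_genotype_clusters(matrix: BetaMatrix, literal_rule: bool = False) -> pd.DataFrame:
    """Assign each (SNP probe, sample) to a genotype cluster by beta thresholds.

    Default rule: beta < 0.25 -> cluster 1; 0.25 <= beta <= 0.75 -> cluster 2;
    beta > 0.75 -> cluster 3. With ``literal_rule=True`` cluster 2 is
    0.25-0.50 and betas in (0.50, 0.75] are left unassigned (NaN).
    """
    snp = matrix.snp_probes()
    if snp.empty:
        raise ValidationError("no SNP probes flagged in site metadata")
    long = snp.stack().rename("beta").reset_index()
    long.columns = ["probe", "sample", "beta"]
    long["lab"] = long["sample"].map(matrix.sample_meta["lab"])
    b = long["beta"].to_numpy(dtype=float)
    cluster = np.full(len(long), np.nan)
    cluster[b < 0.25] = 1
    upper2 = 0.50 if literal_rule else 0.75
    cluster[(b >= 0.25) & (b <= upper2)] = 2
    cluster[b > 0.75] = 3
    long["cluster"] = cluster
    return long


def technical_variance_threshold(
    matrix: BetaMatrix, per_lab: bool = False, literal_rule: bool = False
):
    """95th percentile of within-(lab, probe, genotype-cluster) beta variances.

    Clusters are formed within each lab separately; clusters with fewer than
    two samples are skipped. Variances use the n−1 denominator; the percentile
    uses linear interpolation between order statistics.

    Returns (threshold, variances Series). With ``per_lab=True`` the threshold
    is a dict per lab instead of one pooled value.
    """
    long = snp_genotype_clusters(matrix, literal_rule=literal_rule)
    long = long.dropna(subset=["cluster"])
    grouped = long.groupby(["lab", "probe", "cluster"])["beta"]
    sizes = grouped.size()
    variances = grouped.var(ddof=1)[sizes >= 2]
    if variances.empty:
        raise ValidationError("no genotype cluster has >= 2 samples")
    if per_lab:
        thr = {
            lab: float(np.percentile(v.to_numpy(), 95))
            for lab, v in variances.groupby(level="lab")
        }
        return thr, variances
    return float(np.percentile(variances.to_numpy(), 95)), variances


def classify_low_varying(matrix: BetaMatrix, threshold: float) -> pd.Series:
    """Label each non-SNP site low|high: low iff across-sample variance < threshold."""
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    sites = matrix.autosomal_probes()
    var = sites.var(axis=1, ddof=1, skipna=True)
    return pd.Series(np.where(var < threshold, "low", "high"), index=sites.index, name="label")


def site_variances(matrix: BetaMatrix) -> pd.Series:
    sites = matrix.autosomal_probes()
    return sites.var(axis=1, ddof=1, skipna=True)
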