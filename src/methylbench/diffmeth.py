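"""Per-site differential methylation between two groups of genomes and the
cross-assay concordance framework.

The test is a binomial GLM of (n_meth, n_unmeth) on a group indicator with
a likelihood-ratio (deviance) statistic against the intercept-only model,
chi-squared with 1 df. For this single-binary-covariate design the MLE fits
each group at its pooled proportion, so the vectorized path used for whole
call sets computes the statistic in closed form; ``fit_site`` runs the
generic IRLS and agrees with it (and with reference GLM implementations) to
numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, xlogy

from .errors import ValidationError
from .methylio import MethylCallSet

#: cap on the |logit-scale coefficient| used under separation
COEF_CAP = 15.0


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _coverage_matrix(callsets) -> pd.DataFrame:
    frames = []
    for i, cs in enumerate(callsets):
        df = cs.records.set_index(["chrom", "start"])
        frames.append((df["n_meth"] + df["n_unmeth"]).rename(i))
    return pd.concat(frames, axis=1).fillna(0)


def site_filter(
    group1_callsets,
    group2_callsets,
    min_cov: int = 5,
    min_samples: int = 2,
) -> pd.MultiIndex:
    """Sites where each group has >= min_samples members covered >= min_cov."""
    if len(group1_callsets) < min_samples or len(group2_callsets) < min_samples:
        raise ValidationError(f"each group needs at least {min_samples} samples")
    cov1 = _coverage_matrix(group1_callsets)
    cov2 = _coverage_matrix(group2_callsets)
    idx = cov1.index.union(cov2.index).sort_values()
    ok1 = (cov1.reindex(idx, fill_value=0) >= min_cov).sum(axis=1) >= min_samples
    ok2 = (cov2.reindex(idx, fill_value=0) >= min_cov).sum(axis=1) >= min_samples
    return idx[(ok1 & ok2).to_numpy()]


# ---------------------------------------------------------------------------
# the per-site test
# ---------------------------------------------------------------------------

def _binom_dev(y: np.ndarray, n: np.ndarray, mu: np.ndarray) -> float:
    """Binomial deviance of fitted probabilities mu (saturated minus model)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term = xlogy(y, y / (n * mu)) + xlogy(n - y, (n - y) / (n * (1.0 - mu)))
    return float(2.0 * np.nansum(term))


def fit_site(n_meth, n_unmeth, groups) -> tuple[float, float]:
    """Binomial GLM LRT for one site: deviance statistic and p-value.

    ``groups`` is a 0/1 indicator per sample. Fit is by IRLS with the
    coefficient magnitude capped at +/-15 on the logit scale (separation
    guard). Returns (statistic, p) with p from chi2(1).
    """
    y = np.asarray(n_meth, dtype=float)
    u = np.asarray(n_unmeth, dtype=float)
    g = np.asarray(groups, dtype=float)
    n = y + u
    use = n > 0
    y, u, n, g = y[use], u[use], n[use], g[use]
    if len(np.unique(g)) < 2:
        raise ValidationError("need samples from both groups")

    total_y, total_n = y.sum(), n.sum()
    if total_y == 0 or total_y == total_n:
        return 0.0, 1.0  # all-zero / all-full in both groups: no effect testable

    x = np.column_stack([np.ones_like(g), g])
    beta = np.zeros(2)
    mu_start = (y + 0.5) / (n + 1.0)
    eta = np.log(mu_start / (1.0 - mu_start))
    beta = np.linalg.lstsq(x, eta, rcond=None)[0]
    for _ in range(100):
        eta = np.clip(x @ beta, -30, 30)
        mu = expit(eta)
        w = n * mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        z = eta + (y - n * mu) / w
        xtw = x.T * w
        new_beta = np.linalg.solve(xtw @ x, xtw @ z)
        new_beta = np.clip(new_beta, -COEF_CAP, COEF_CAP)
        if np.max(np.abs(new_beta - beta)) < 1e-12:
            beta = new_beta
            break
        beta = new_beta

    mu_full = expit(np.clip(x @ beta, -30, 30))
    p0 = total_y / total_n
    dev_full = _binom_dev(y, n, mu_full)
    dev_null = _binom_dev(y, n, np.full_like(y, p0))
    stat = max(0.0, dev_null - dev_full)
    return stat, float(stats.chi2.sf(stat, df=1))


def _lrt_vectorized(m1, n1, m2, n2):
    """Closed-form LRT over arrays of per-group pooled counts."""
    m1, n1, m2, n2 = (np.asarray(a, dtype=float) for a in (m1, n1, m2, n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(n1 > 0, m1 / n1, 0.0)
        p2 = np.where(n2 > 0, m2 / n2, 0.0)
        p0 = (m1 + m2) / (n1 + n2)
    ll = (
        xlogy(m1, p1) + xlogy(n1 - m1, 1 - p1)
        + xlogy(m2, p2) + xlogy(n2 - m2, 1 - p2)
        - xlogy(m1 + m2, p0) - xlogy((n1 - m1) + (n2 - m2), 1 - p0)
    )
    stat = np.maximum(0.0, 2.0 * ll)
    return stat, stats.chi2.sf(stat, df=1)


# ---------------------------------------------------------------------------
# multiplicity + effect size
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def pmd(n_meth, n_unmeth, groups) -> float:
    """Difference of group-pooled methylation proportions (group1 − group0)."""
    y = np.asarray(n_meth, dtype=float)
    u = np.asarray(n_unmeth, dtype=float)
    g = np.asarray(groups)
    n = y + u
    out = []
    for level in (1, 0):
        sel = g == level
        tot = n[sel].sum()
        if tot == 0:
            raise ValidationError("a group has no observations at this site")
        out.append(y[sel].sum() / tot)
    return float(out[0] - out[1])


# ---------------------------------------------------------------------------
# whole-call-set analysis
# ---------------------------------------------------------------------------

def dm_analysis(
    group1_callsets,
    group2_callsets,
    alpha: float = 0.05,
    min_cov: int = 5,
    min_samples: int = 2,
    pmd_threshold: float | None = None,
) -> pd.DataFrame:
    """Per-site DM table: group counts, LRT statistic, p, BH q, PMD, flags.

    Only sites passing the coverage filter are tested and enter the BH
    correction. ``significant`` is q < alpha, additionally requiring
    |PMD| >= pmd_threshold when one is given.
    """
    retained = site_filter(group1_callsets, group2_callsets, min_cov, min_samples)

    def pooled(callsets):
        frames = [cs.records.set_index(["chrom", "start"])[["n_meth", "n_unmeth"]]
                  for cs in callsets]
        big = pd.concat(frames).groupby(level=[0, 1]).sum()
        return big.reindex(retained, fill_value=0)

    g1 = pooled(group1_callsets)
    g2 = pooled(group2_callsets)
    n1 = (g1["n_meth"] + g1["n_unmeth"]).to_numpy(float)
    n2 = (g2["n_meth"] + g2["n_unmeth"]).to_numpy(float)
    m1 = g1["n_meth"].to_numpy(float)
    m2 = g2["n_meth"].to_numpy(float)

    stat, p = _lrt_vectorized(m1, n1, m2, n2)
    q = bh_adjust(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmd_vals = m1 / n1 - m2 / n2
    out = pd.DataFrame(
        {
            "chrom": retained.get_level_values(0),
            "start": retained.get_level_values(1),
            "n_meth_g1": m1.astype(np.int64),
            "n_total_g1": n1.astype(np.int64),
            "n_meth_g2": m2.astype(np.int64),
            "n_total_g2": n2.astype(np.int64),
            "stat": stat,
            "p": p,
            "q": q,
            "pmd": pmd_vals,
        }
    )
    sig = out["q"] < alpha
    if pmd_threshold is not None:
        sig &= out["pmd"].abs() >= pmd_threshold
    out["significant"] = sig
    return out


def dma_set(dm_table: pd.DataFrame) -> set[tuple]:
    """Significant sites of one assay's DM table as a set of (chrom, start)."""
    sig = dm_table[dm_table["significant"]]
    return set(zip(sig["chrom"], sig["start"]))


# ---------------------------------------------------------------------------
# concordance framework
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceReport:
    """Per-assay DMA agreement metrics against the DMk+ consensus.

    ``dmk_total`` collects sites called by >= k assays overall; the
    "k other" variant per assay counts sites called by >= k−1 assays other
    than itself.
    """

    k: int
    universe_size: int
    dma_sizes: dict[str, int]
    unique_fraction: dict[str, float]
    dmk_total: set
    dmk_size: int
    specificity: dict[str, float]  # |DMA ∩ DMk+| / |DMA|
    sensitivity: dict[str, float]  # |DMA ∩ DMk+| / |DMk+|
    specificity_other: dict[str, float]
    sensitivity_other: dict[str, float]

    def to_json_dict(self) -> dict:
        return {
            "k": self.k,
            "universe_size": self.universe_size,
            "dmk_size": self.dmk_size,
            "per_assay": {
                a: {
                    "n_dma": self.dma_sizes[a],
                    "unique_fraction": self.unique_fraction[a],
                    "specificity": self.specificity[a],
                    "sensitivity": self.sensitivity[a],
                    "specificity_k_other": self.specificity_other[a],
                    "sensitivity_k_other": self.sensitivity_other[a],
                }
                for a in self.dma_sizes
            },
        }


def concordance(dma_sets: dict[str, set], universe, k: int = 4) -> ConcordanceReport:
    """DMA/DMk+ agreement metrics over a common analyzed-site universe."""
    universe = set(universe)
    if not universe:
        raise ValidationError("empty site universe")
    if len(dma_sets) < 2:
        raise ValidationError("need at least 2 assays")
    dma = {a: set(s) & universe for a, s in dma_sets.items()}
    names = list(dma)

    call_count: dict = {}
    for s in dma.values():
        for site in s:
            call_count[site] = call_count.get(site, 0) + 1
    dmk = {site for site, c in call_count.items() if c >= k}

    unique_fraction, spec, sens, spec_o, sens_o, sizes = {}, {}, {}, {}, {}, {}
    for a in names:
        s = dma[a]
        sizes[a] = len(s)
        unique = {site for site in s if call_count[site] == 1}
        unique_fraction[a] = len(unique) / len(s) if s else float("nan")
        inter = len(s & dmk)
        spec[a] = inter / len(s) if s else float("nan")
        sens[a] = inter / len(dmk) if dmk else float("nan")
        # "k other": sites called by >= k-1 assays excluding this one
        other = {site for site, c in call_count.items()
                 if c - (1 if site in s else 0) >= k - 1}
        inter_o = len(s & other)
        spec_o[a] = inter_o / len(s) if s else float("nan")
        sens_o[a] = inter_o / len(other) if other else float("nan")
    return ConcordanceReport(
        k=k,
        universe_size=len(universe),
        dma_sizes=sizes,
        unique_fraction=unique_fraction,
        dmk_total=dmk,
        dmk_size=len(dmk),
        specificity=spec,
        sensitivity=sens,
        specificity_other=spec_o,
        sensitivity_other=sens_o,
    )


def agreement_by_coverage(
    dma_sets: dict[str, set],
    median_coverage: dict,
    n_bins: int = 5,
    percentile_range: tuple[float, float] = (5.0, 95.0),
) -> dict[str, pd.DataFrame]:
    """Per assay: DMA sites cross-tabulated by (assays agreeing) x coverage bin.

    Rows are the number of assays (1..n) that called the site; columns are
    equal-width bins of median coverage between the assay's DMA-site 5th and
    95th coverage percentiles. Sites outside that range are excluded.
    """
    call_count: dict = {}
    for s in dma_sets.values():
        for site in s:
            call_count[site] = call_count.get(site, 0) + 1
    n_assays = len(dma_sets)
    lo_pct, hi_pct = percentile_range
    out = {}
    for assay, s in dma_sets.items():
        sites = [site for site in s if site in median_coverage]
        if not sites:
            out[assay] = pd.DataFrame()
            continue
        cov = np.array([median_coverage[site] for site in sites], dtype=float)
        lo = np.percentile(cov, lo_pct)
        hi = np.percentile(cov, hi_pct)
        keep = (cov >= lo) & (cov <= hi)
        cov_k = cov[keep]
        agree = np.array([call_count[site] for site in sites])[keep]
        edges = np.linspace(lo, hi, n_bins + 1)
        bin_idx = np.clip(np.searchsorted(edges, cov_k, side="right") - 1, 0, n_bins - 1)
        table = np.zeros((n_assays, n_bins), dtype=int)
        for a, b in zip(agree, bin_idx):
            table[a - 1, b] += 1
        out[assay] = pd.DataFrame(
            table,
            index=pd.Index(range(1, n_assays + 1), name="assays_agreeing"),
            columns=[f"[{edges[i]:.3g},{edges[i+1]:.3g})" for i in range(n_bins)],
        )
    return out


# ---------------------------------------------------------------------------
# array-side effect sizes
# ---------------------------------------------------------------------------

def array_pmd(beta_matrix, group1_genomes, group2_genomes) -> pd.Series:
    """Per-site array PMD: group mean of per-genome replicate means.

    Genome means weight each genome equally regardless of replicate count,
    matching the balanced random-intercept-per-genome group-effect estimate.
    Genomes absent from the matrix are omitted with a warning.
    """
    import warnings

    meta = beta_matrix.sample_meta
    values = beta_matrix.values

    def group_mean(genomes):
        genome_means = []
        for g in genomes:
            cols = meta.index[meta["cell_line"] == g]
            if len(cols) == 0:
                warnings.warn(f"genome {g!r} has no array samples; omitted")
                continue
            genome_means.append(values[cols].mean(axis=1))
        if not genome_means:
            raise ValidationError("no genomes of a group present in the matrix")
        return pd.concat(genome_means, axis=1).mean(axis=1)

    return (group_mean(group1_genomes) - group_mean(group2_genomes)).rename("array_pmd")


def array_seq_dm_agreement(
    dma_sets: dict[str, set],
    array_pmds: pd.Series,
    threshold: float = 0.2,
) -> pd.DataFrame:
    """Cross-platform agreement between sequencing DMAs and array PMDs.

    Per assay: fraction of its DMA sites (within the probe universe) with
    array |PMD| >= threshold, and the reverse fraction of large-|PMD| probes
    that are DMAs.
    """
    probe_universe = set(array_pmds.index)
    large = {site for site, v in array_pmds.items() if abs(v) >= threshold}
    rows = []
    for assay, s in dma_sets.items():
        in_universe = set(s) & probe_universe
        frac_dma = len(in_universe & large) / len(in_universe) if in_universe else float("nan")
        frac_rev = len(in_universe & large) / len(large) if large else float("nan")
        rows.append((assay, len(in_universe), frac_dma, frac_rev))
    return pd.DataFrame(
        rows, columns=["assay", "n_dma_on_array", "frac_dma_with_array_pmd", "frac_array_pmd_dma"]
    ).set_index("assay")
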