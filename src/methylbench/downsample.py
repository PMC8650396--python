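"""Coverage normalization by count-level binomial thinning, with the
read-level (BAM-analogue) route for comparison.

Count-level thinning keeps each methylated and unmethylated observation
independently with probability f = target / current mean. Read-level
thinning keeps whole reads with probability f, so observations within a
multi-site read survive or vanish together, which inflates the variance of
the achieved mean coverage — this module quantifies that difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .methylio import MethylCallSet
from .synthio import ReadSet, stream_rng


def _current_mean(callset: MethylCallSet, reference_cpg_set=None) -> float:
    cov = callset.coverage
    if reference_cpg_set is not None:
        ref = reference_cpg_set[["chrom", "pos"]] if isinstance(reference_cpg_set, pd.DataFrame) \
            else pd.DataFrame(list(reference_cpg_set), columns=["chrom", "pos"])
        obs = callset.records[["chrom", "start"]].rename(columns={"start": "pos"})
        obs = obs.assign(coverage=cov)
        merged = ref.merge(obs, on=["chrom", "pos"], how="inner")
        cov = merged["coverage"].to_numpy()
    if cov.size == 0:
        raise ValidationError("call set has no covered sites to compute mean coverage")
    return float(cov.mean())


def thin_counts(
    callset: MethylCallSet,
    target_mean: float,
    reference_cpg_set=None,
    seed: int = 0,
) -> MethylCallSet:
    """Binomially thin per-site counts to a target mean coverage.

    Per site, retained methylated ~ Binomial(n_meth, f) and retained
    unmethylated ~ Binomial(n_unmeth, f) independently, with
    f = target_mean / current mean over covered (reference) CpGs. Sites
    reduced to zero coverage are dropped. If the current mean is already at
    or below the target the call set is returned unchanged with a warning.
    """
    if target_mean <= 0:
        raise ValidationError("target_mean must be > 0")
    current = _current_mean(callset, reference_cpg_set)
    f = target_mean / current
    if f >= 1.0:
        if f > 1.0:
            warnings.warn(
                f"current mean coverage {current:.2f} below target {target_mean}; returning input"
            )
        return MethylCallSet(callset.records.copy(), dict(callset.metadata))
    rng = stream_rng(seed, "thin_counts")
    df = callset.records.copy()
    df["n_meth"] = rng.binomial(df["n_meth"].to_numpy(), f)
    df["n_unmeth"] = rng.binomial(df["n_unmeth"].to_numpy(), f)
    df = df[(df["n_meth"] + df["n_unmeth"]) > 0].reset_index(drop=True)
    meta = dict(callset.metadata)
    meta["downsampled_to"] = target_mean
    return MethylCallSet(df, meta)


def thin_reads(readset: ReadSet, target_mean: float, seed: int = 0) -> MethylCallSet:
    """Thin whole reads with probability f, then aggregate to a call set."""
    if target_mean <= 0:
        raise ValidationError("target_mean must be > 0")
    current = _current_mean(readset.callset)
    f = target_mean / current
    if f >= 1.0:
        if f > 1.0:
            warnings.warn(
                f"current mean coverage {current:.2f} below target {target_mean}; returning input"
            )
        return readset.aggregate()
    rng = stream_rng(seed, "thin_reads")
    keep = rng.random(readset.n_reads) < f
    out = readset.aggregate(read_mask=keep)
    out.metadata["downsampled_to"] = target_mean
    return out


def beta_extreme_fraction(callset: MethylCallSet) -> float:
    """Fraction of sites with estimated beta exactly 0 or 1."""
    beta = callset.beta
    return float(np.mean((beta == 0.0) | (beta == 1.0)))


@dataclass
class DownsamplingComparison:
    target_mean: float
    count_route_means: np.ndarray
    read_route_means: np.ndarray
    count_route_abs_error: np.ndarray
    read_route_abs_error: np.ndarray
    count_route_site_counts: np.ndarray
    read_route_site_counts: np.ndarray
    count_route_extreme_fraction: np.ndarray
    read_route_extreme_fraction: np.ndarray

    @property
    def count_route_wins(self) -> int:
        """Trials in which count-level thinning hit the target mean at least
        as accurately as read-level thinning."""
        return int(np.sum(self.count_route_abs_error <= self.read_route_abs_error))

    def summary(self) -> dict:
        return {
            "target_mean": self.target_mean,
            "n_trials": len(self.count_route_means),
            "count_route": {
                "mean_abs_error": float(self.count_route_abs_error.mean()),
                "mean_sites": float(self.count_route_site_counts.mean()),
                "mean_extreme_fraction": float(self.count_route_extreme_fraction.mean()),
            },
            "read_route": {
                "mean_abs_error": float(self.read_route_abs_error.mean()),
                "mean_sites": float(self.read_route_site_counts.mean()),
                "mean_extreme_fraction": float(self.read_route_extreme_fraction.mean()),
            },
            "count_route_wins": self.count_route_wins,
        }


def compare_downsampling(
    callset: MethylCallSet,
    readset: ReadSet,
    target_mean: float,
    n_trials: int = 50,
    seed: int = 0,
) -> DownsamplingComparison:
    """Paired trials of count-level vs read-level thinning to one target."""
    agg = readset.aggregate()
    if not agg.records[["chrom", "start", "n_meth", "n_unmeth"]].equals(
        callset.records[["chrom", "start", "n_meth", "n_unmeth"]]
    ):
        raise ValidationError("read set does not aggregate to the supplied call set")
    current = _current_mean(callset)
    if current < target_mean:
        raise ValidationError("current mean coverage below target")
    f = target_mean / current

    c_means, r_means, c_sites, r_sites, c_ext, r_ext = ([] for _ in range(6))
    counts_m = callset.records["n_meth"].to_numpy()
    counts_u = callset.records["n_unmeth"].to_numpy()
    n_sites = len(callset)
    for t in range(n_trials):
        rng_c = stream_rng(seed, "cmp_counts", t)
        m = rng_c.binomial(counts_m, f)
        u = rng_c.binomial(counts_u, f)
        cov = m + u
        covered = cov > 0
        c_means.append(cov[covered].mean())
        c_sites.append(int(covered.sum()))
        beta = m[covered] / cov[covered]
        c_ext.append(float(np.mean((beta == 0) | (beta == 1))))

        rng_r = stream_rng(seed, "cmp_reads", t)
        keep = rng_r.random(readset.n_reads) < f
        keep_obs = keep[readset.obs_read]
        site = readset.obs_site[keep_obs]
        meth_flags = readset.obs_meth[keep_obs]
        cov_r = np.bincount(site, minlength=n_sites)
        m_r = np.bincount(site[meth_flags], minlength=n_sites)
        covered_r = cov_r > 0
        r_means.append(cov_r[covered_r].mean())
        r_sites.append(int(covered_r.sum()))
        beta_r = m_r[covered_r] / cov_r[covered_r]
        r_ext.append(float(np.mean((beta_r == 0) | (beta_r == 1))))

    c_means = np.asarray(c_means)
    r_means = np.asarray(r_means)
    return DownsamplingComparison(
        target_mean=target_mean,
        count_route_means=c_means,
        read_route_means=r_means,
        count_route_abs_error=np.abs(c_means - target_mean),
        read_route_abs_error=np.abs(r_means - target_mean),
        count_route_site_counts=np.asarray(c_sites),
        read_route_site_counts=np.asarray(r_sites),
        count_route_extreme_fraction=np.asarray(c_ext),
        read_route_extreme_fraction=np.asarray(r_ext),
    )
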