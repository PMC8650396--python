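import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methylbench.diffmeth import (
    _lrt_vectorized,
    agreement_by_coverage,
    array_pmd,
    array_seq_dm_agreement,
    bh_adjust,
    concordance,
    dm_analysis,
    dma_set,
    fit_site,
    pmd,
    site_filter,
)
from methylbench.errors import ValidationError
from methylbench.synthio import SimConfig, ArrayConfig, generate_array

from conftest import make_callset


def _group_callsets(cov_lists, seed=0):
    """Callsets over shared sites with per-sample coverage vectors."""
    rng = np.random.default_rng(seed)
    out = []
    for covs in cov_lists:
        covs = np.asarray(covs)
        starts = np.arange(len(covs)) * 2
        keep = covs > 0
        m = rng.binomial(covs[keep], 0.5)
        out.append(make_callset(["chr1"] * int(keep.sum()), starts[keep], m, covs[keep] - m))
    return out


class TestSiteFilter:
    def test_rule_pass(self):
        g1 = _group_callsets([[6], [4], [5]])
        g2 = _group_callsets([[5], [5], [0]], seed=1)
        retained = site_filter(g1, g2)
        assert len(retained) == 1

    def test_rule_fail_one_group_low(self):
        g1 = _group_callsets([[6], [6], [6]])
        g2 = _group_callsets([[4], [4], [4]], seed=1)
        assert len(site_filter(g1, g2)) == 0

    def test_small_group_rejected(self):
        g1 = _group_callsets([[6]])
        with pytest.raises(ValidationError):
            site_filter(g1, g1)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        n = 100
        cov1 = rng.integers(0, 12, (3, n))
        cov2 = rng.integers(0, 12, (3, n))
        g1 = _group_callsets(list(cov1), seed=2)
        g2 = _group_callsets(list(cov2), seed=3)
        retained = {s for _, s in site_filter(g1, g2)}
        expected = set()
        for i in range(n):
            if (cov1[:, i] >= 5).sum() >= 2 and (cov2[:, i] >= 5).sum() >= 2:
                expected.add(i * 2)
        assert retained == expected


class TestFitSite:
    def test_no_group_effect(self):
        stat, p = fit_site([10, 10, 10, 10], [10, 10, 10, 10], [0, 0, 1, 1])
        assert stat == pytest.approx(0.0, abs=1e-8)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_strong_effect(self):
        stat, p = fit_site([90, 90, 90, 10, 10, 10], [10, 10, 10, 90, 90, 90],
                           [0, 0, 0, 1, 1, 1])
        assert p < 1e-10

    def test_all_zero_both_groups(self):
        stat, p = fit_site([0, 0, 0, 0], [10, 10, 10, 10], [0, 0, 1, 1])
        assert stat == 0.0 and p == 1.0

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        for _ in range(30):
            n = rng.integers(10, 40, 6)
            y = rng.binomial(n, rng.uniform(0.15, 0.85, 6))
            g = np.array([0, 0, 0, 1, 1, 1])
            stat, p = fit_site(y, n - y, g)
            endog = np.column_stack([y, n - y])
            full = sm.GLM(endog, sm.add_constant(g.astype(float)),
                          family=sm.families.Binomial()).fit()
            null = sm.GLM(endog, np.ones((6, 1)), family=sm.families.Binomial()).fit()
            ref = null.deviance - full.deviance
            assert stat == pytest.approx(ref, rel=1e-6, abs=1e-8)

    def test_vectorized_matches_irls(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            n = rng.integers(5, 50, 6)
            y = rng.binomial(n, rng.uniform(0.1, 0.9, 6))
            g = np.array([0, 0, 0, 1, 1, 1])
            stat_i, p_i = fit_site(y, n - y, g)
            m1, n1 = y[g == 1].sum(), n[g == 1].sum()
            m0, n0 = y[g == 0].sum(), n[g == 0].sum()
            stat_v, p_v = _lrt_vectorized([m0], [n0], [m1], [n1])
            assert stat_i == pytest.approx(float(stat_v[0]), rel=1e-6, abs=1e-8)

    def test_separation_handled(self):
        # complete separation: one group all 0, other all full
        stat, p = fit_site([0, 0, 0, 20, 20, 20], [20, 20, 20, 0, 0, 0],
                           [0, 0, 0, 1, 1, 1])
        assert np.isfinite(stat) and stat > 0 and p < 1e-10


class TestBhAdjust:
    def test_hand_computed_example(self):
        q = bh_adjust([0.002, 0.01, 0.03, 0.04])
        assert np.allclose(q, [0.008, 0.02, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_p(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    def test_q_geq_p(self, rng):
        p = rng.uniform(0, 1, 500)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_matches_statsmodels(self, ps):
        from statsmodels.stats.multitest import multipletests

        q = bh_adjust(ps)
        _, q_ref, _, _ = multipletests(ps, method="fdr_bh")
        assert np.allclose(q, q_ref, atol=1e-12)


class TestPmd:
    def test_example(self):
        # pooled 0.80 vs 0.55
        val = pmd([80, 55], [20, 45], [1, 0])
        assert val == pytest.approx(0.25)
        assert abs(val) >= 0.2

    def test_equal_groups_zero(self):
        assert pmd([5, 5], [5, 5], [0, 1]) == 0.0

    def test_hand_pooled_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(1, 30, 6)
            y = rng.binomial(n, 0.5)
            g = np.array([0, 1, 0, 1, 0, 1])
            val = pmd(y, n - y, g)
            p1 = y[g == 1].sum() / n[g == 1].sum()
            p0 = y[g == 0].sum() / n[g == 0].sum()
            assert val == pytest.approx(p1 - p0)


class TestDmAnalysis:
    def test_planted_effect_detected(self):
        from methylbench.synthio import generate_callset, generate_truth

        cfg = SimConfig(seed=23, n_sites=2000, dm_fraction=0.2, dm_pmd=0.4,
                        conversion_error=0.0, spike_ins=())
        truth = generate_truth(cfg)
        g1 = [generate_callset(truth, "EMSeq", g) for g in cfg.groups["A"]]
        g2 = [generate_callset(truth, "EMSeq", g) for g in cfg.groups["B"]]
        table = dm_analysis(g1, g2)
        truth_dm = dict(zip(truth.sites["pos"], truth.sites["dm"]))
        table["is_dm"] = table["start"].map(truth_dm)
        power = table.loc[table["is_dm"], "significant"].mean()
        fdr = (table["significant"] & ~table["is_dm"]).sum() / max(1, table["significant"].sum())
        assert power > 0.7
        assert fdr < 0.1
        assert (table["q"] >= table["p"] - 1e-12).all()
        assert table["pmd"].between(-1, 1).all()


class TestConcordance:
    def test_dm4_membership(self):
        site = ("chr1", 10)
        dma = {a: {site} for a in "ABCD"}
        dma.update({a: set() for a in "EF"})
        rep = concordance(dma, universe={site}, k=4)
        assert site in rep.dmk_total

    def test_disjoint_assay(self):
        dma = {"A": {("chr1", 2)}, "B": {("chr1", 4)}, "C": {("chr1", 4)},
               "D": {("chr1", 4)}, "E": {("chr1", 4)}, "F": {("chr1", 4)}}
        universe = {("chr1", 2), ("chr1", 4)}
        rep = concordance(dma, universe, k=4)
        assert rep.unique_fraction["A"] == 1.0
        assert rep.specificity["A"] == 0.0

    def test_nested_dmk(self):
        rng = np.random.default_rng(3)
        universe = [("chr1", i) for i in range(100)]
        dma = {a: {s for s in universe if rng.random() < 0.4} for a in "ABCDEF"}
        prev = None
        for k in (2, 3, 4, 5, 6):
            rep = concordance(dma, universe, k=k)
            if prev is not None:
                assert rep.dmk_total <= prev
            prev = rep.dmk_total

    def test_brute_force_200_configs(self):
        rng = np.random.default_rng(29)
        names = list("ABCDEF")
        for trial in range(200):
            universe = [("chr1", i) for i in range(30)]
            dma = {a: {s for s in universe if rng.random() < rng.uniform(0.1, 0.6)}
                   for a in names}
            k = int(rng.integers(2, 6))
            rep = concordance(dma, universe, k=k)
            dmk = {s for s in universe
                   if sum(s in dma[a] for a in names) >= k}
            assert rep.dmk_total == dmk
            for a in names:
                s = dma[a]
                if s:
                    unique = sum(
                        1 for site in s
                        if all(site not in dma[o] for o in names if o != a)
                    )
                    assert rep.unique_fraction[a] == pytest.approx(unique / len(s))
                    assert rep.specificity[a] == pytest.approx(len(s & dmk) / len(s))
                if dmk:
                    assert rep.sensitivity[a] == pytest.approx(len(s & dmk) / len(dmk))
                other = {site for site in universe
                         if sum(site in dma[o] for o in names if o != a) >= k - 1}
                if s:
                    assert rep.specificity_other[a] == pytest.approx(len(s & other) / len(s))

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            concordance({"A": set(), "B": set()}, universe=set())


class TestAgreementByCoverage:
    def test_all_agree(self):
        sites = [("chr1", i) for i in range(50)]
        dma = {a: set(sites) for a in "ABCDEF"}
        cov = {s: 10.0 + i for i, s in enumerate(sites)}
        tables = agreement_by_coverage(dma, cov, n_bins=4)
        for a in dma:
            tab = tables[a]
            assert tab.loc[1:5].to_numpy().sum() == 0
            assert tab.loc[6].sum() > 0

    def test_brute_force_tabulation(self):
        rng = np.random.default_rng(31)
        sites = [("chr1", i) for i in range(200)]
        dma = {a: {s for s in sites if rng.random() < 0.5} for a in "ABCDEF"}
        cov = {s: float(rng.uniform(5, 100)) for s in sites}
        n_bins = 5
        tables = agreement_by_coverage(dma, cov, n_bins=n_bins)
        count = {s: sum(s in dma[a] for a in dma) for s in sites}
        for a, tab in tables.items():
            mine = [s for s in dma[a]]
            covs = np.array([cov[s] for s in mine])
            lo, hi = np.percentile(covs, 5), np.percentile(covs, 95)
            keep = [(s, c) for s, c in zip(mine, covs) if lo <= c <= hi]
            assert tab.to_numpy().sum() == len(keep)
            edges = np.linspace(lo, hi, n_bins + 1)
            oracle = np.zeros((6, n_bins), dtype=int)
            for s, c in keep:
                b = min(n_bins - 1, max(0, np.searchsorted(edges, c, side="right") - 1))
                oracle[count[s] - 1, b] += 1
            assert (tab.to_numpy() == oracle).all()


class TestArrayPmd:
    @pytest.fixture
    def matrix(self):
        cfg = SimConfig(seed=37, array=ArrayConfig(
            n_sites=50, var_cellline=0.02, var_lab=0.0, var_residual=0.001))
        return generate_array(cfg)

    def test_balanced_difference(self):
        cfg = SimConfig(seed=41, array=ArrayConfig(
            n_sites=5, var_cellline=0.0, var_lab=0.0, var_residual=0.0,
            cell_lines=("X1", "X2", "X3", "Y1", "Y2", "Y3"), trios=()))
        bm = generate_array(cfg)
        vals = bm.values.copy()
        meta = bm.sample_meta
        auto = ~bm.site_meta["is_snp_probe"]
        for cl, delta in [("X1", 0.3), ("X2", 0.3), ("X3", 0.3)]:
            cols = meta.index[meta["cell_line"] == cl]
            vals.loc[auto.to_numpy(), cols] = np.clip(
                vals.loc[auto.to_numpy(), cols] * 0 + 0.8, 0, 1)
        for cl in ("Y1", "Y2", "Y3"):
            cols = meta.index[meta["cell_line"] == cl]
            vals.loc[auto.to_numpy(), cols] = 0.5
        bm.values = vals
        res = array_pmd(bm, ["X1", "X2", "X3"], ["Y1", "Y2", "Y3"])
        auto_idx = bm.site_meta.index[auto]
        assert np.allclose(res.loc[auto_idx], 0.3)

    def test_genome_equal_weighting_with_unequal_replicates(self):
        # genome means weighted equally even with different replicate counts
        values = pd.DataFrame(
            {
                "g1_r1": [0.8], "g1_r2": [0.8], "g1_r3": [0.8],
                "g2_r1": [0.6],
                "g3_r1": [0.4], "g3_r2": [0.4],
            },
            index=["cg1"],
        )
        site_meta = pd.DataFrame({"is_snp_probe": [False]}, index=["cg1"])
        sample_meta = pd.DataFrame(
            {
                "cell_line": ["g1", "g1", "g1", "g2", "g3", "g3"],
                "lab": ["L"] * 6,
                "replicate": [1, 2, 3, 1, 1, 2],
            },
            index=values.columns,
        )
        from methylbench.arrayqc import BetaMatrix
        bm = BetaMatrix(values, site_meta, sample_meta)
        res = array_pmd(bm, ["g1", "g2"], ["g3"])
        assert res.iloc[0] == pytest.approx((0.8 + 0.6) / 2 - 0.4)

    def test_matches_mixed_model_oracle(self, matrix):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        groups1 = ["HG002", "HG003", "HG004"]
        groups2 = ["HG005", "HG006", "HG007"]
        res = array_pmd(matrix, groups1, groups2)
        meta = matrix.sample_meta
        keep = meta["cell_line"].isin(groups1 + groups2)
        for probe in matrix.values.index[:5]:
            df = pd.DataFrame(
                {
                    "y": matrix.values.loc[probe, keep.to_numpy()],
                    "genome": meta.loc[keep, "cell_line"].to_numpy(),
                    "grp": meta.loc[keep, "cell_line"].isin(groups1).astype(float).to_numpy(),
                }
            )
            md = smf.mixedlm("y ~ grp", df, groups=df["genome"]).fit(reml=True)
            assert res.loc[probe] == pytest.approx(md.params["grp"], abs=1e-6)

    def test_missing_genome_warns(self, matrix):
        with pytest.warns(UserWarning):
            array_pmd(matrix, ["HG002", "NOPE"], ["HG005"])


class TestArraySeqAgreement:
    def test_threshold_zero(self):
        pmds = pd.Series({("chr1", 2): 0.1, ("chr1", 4): -0.05})
        dma = {"A": {("chr1", 2), ("chr1", 4)}}
        out = array_seq_dm_agreement(dma, pmds, threshold=0.0)
        assert out.loc["A", "frac_dma_with_array_pmd"] == 1.0

    def test_no_overlap(self):
        pmds = pd.Series({("chr1", 2): 0.5})
        dma = {"A": {("chr1", 2)}}
        out = array_seq_dm_agreement(dma, pmds, threshold=0.9)
        assert out.loc["A", "frac_dma_with_array_pmd"] == 0.0

    def test_brute_force(self):
        rng = np.random.default_rng(43)
        sites = [("chr1", i) for i in range(100)]
        pmds = pd.Series({s: rng.uniform(-0.5, 0.5) for s in sites})
        dma = {a: {s for s in sites if rng.random() < 0.3} for a in "AB"}
        thr = 0.2
        out = array_seq_dm_agreement(dma, pmds, threshold=thr)
        for a in dma:
            hits = sum(1 for s in dma[a] if abs(pmds[s]) >= thr)
            assert out.loc[a, "frac_dma_with_array_pmd"] == pytest.approx(hits / len(dma[a]))
            large = [s for s in sites if abs(pmds[s]) >= thr]
            rev = sum(1 for s in large if s in dma[a])
            assert out.loc[a, "frac_array_pmd_dma"] == pytest.approx(rev / len(large))
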