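import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import epistate as ep
from epistate.imputation import (ScanResult, class_max_r2, permutation_null,
                                 transcript_rng, uniformity_check)


def _one_hot_founder(rng, F=8, L=5, P=10):
    arr = np.zeros((F, L, P))
    states = rng.integers(0, L, size=(F, P))
    for f in range(F):
        arr[f, states[f], np.arange(P)] = 1.0
    return arr


class TestImputeFeature:
    def test_one_hot_haplotype_reproduces_founder_exactly(self):
        rng = np.random.default_rng(0)
        founder = _one_hot_founder(rng)
        haps = np.zeros((3, 8))
        haps[:, 2] = 1.0  # every individual is pure founder 3
        imputed = ep.impute_feature(haps, founder)
        assert (imputed == founder[2][None]).all()

    def test_even_mixture_of_two_founders(self):
        founder = np.zeros((2, 3, 1))
        founder[0, 0, 0] = 1.0  # founder 1 carries state 1
        founder[1, 1, 0] = 1.0  # founder 2 carries state 2
        imputed = ep.impute_feature(np.array([[0.5, 0.5]]), founder)
        assert np.allclose(imputed[0, :, 0], [0.5, 0.5, 0.0])

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(15):
            n, F, L, P = (int(rng.integers(2, 6)) for _ in range(4))
            haps = rng.dirichlet(np.ones(F), size=n)
            founder = rng.normal(size=(F, L, P))
            fast = ep.impute_feature(haps, founder)
            slow = np.zeros((n, L, P))
            for i in range(n):
                for l in range(L):
                    for p in range(P):
                        for f in range(F):
                            slow[i, l, p] += haps[i, f] * founder[f, l, p]
            assert np.allclose(fast, slow, atol=1e-12)

    @given(alpha=st.floats(0, 1))
    @settings(max_examples=25, deadline=None)
    def test_linear_in_haplotypes(self, alpha):
        rng = np.random.default_rng(7)
        founder = rng.normal(size=(4, 2, 3))
        h1 = rng.dirichlet(np.ones(4), size=5)
        h2 = rng.dirichlet(np.ones(4), size=5)
        mixed = ep.impute_feature(alpha * h1 + (1 - alpha) * h2, founder)
        parts = alpha * ep.impute_feature(h1, founder) + \
            (1 - alpha) * ep.impute_feature(h2, founder)
        assert np.allclose(mixed, parts, atol=1e-10)

    def test_one_hot_level_sums_stay_one(self):
        rng = np.random.default_rng(1)
        founder = _one_hot_founder(rng)
        haps = rng.dirichlet(np.ones(8), size=20)
        imputed = ep.impute_feature(haps, founder)
        assert np.allclose(imputed.sum(axis=1), 1.0, atol=1e-9)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            ep.impute_feature(np.ones((3, 7)), np.ones((8, 2, 2)))


class TestResidualize:
    def test_no_covariates_just_centers(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert np.allclose(ep.residualize(x, None), x - 2.5)

    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(3)
        C = rng.normal(size=(50, 2))
        x = rng.normal(size=(50, 3, 4))
        r = ep.residualize(x, C)
        flat = r.reshape(50, -1)
        assert np.abs(C.T @ flat).max() < 1e-8

    def test_simulated_sex_effect_removed(self):
        rng = np.random.default_rng(4)
        sex = np.tile([0, 1], 100)
        y = 2.0 * sex + rng.normal(0, 0.3, 200)
        r = ep.residualize(y, sex)
        assert abs(r[sex == 1].mean() - r[sex == 0].mean()) < 0.05

    def test_collinear_covariates_warn_but_work(self):
        rng = np.random.default_rng(5)
        c = rng.normal(size=30)
        C = np.column_stack([c, 2 * c])
        with pytest.warns(UserWarning, match="rank"):
            r = ep.residualize(rng.normal(size=30), C)
        assert np.abs(C.T @ r).max() < 1e-8


class TestSingleDfScan:
    def test_matches_statsmodels_per_cell(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(6)
        y = rng.normal(size=40)
        X = rng.normal(size=(40, 2, 3))
        scan = ep.single_df_scan(y - y.mean(), X)
        for l in range(2):
            for p in range(3):
                fit = sm.OLS(y - y.mean(), sm.add_constant(X[:, l, p])).fit()
                assert scan.beta[l, p] == pytest.approx(fit.params[1], abs=1e-10)
                assert scan.r2[l, p] == pytest.approx(fit.rsquared, abs=1e-10)

    def test_duplicated_predictor_gives_identical_r2(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=30)
        x = rng.normal(size=30)
        X = np.stack([x, x], axis=1)[:, :, None]
        scan = ep.single_df_scan(y, X)
        assert scan.r2[0, 0] == scan.r2[1, 0]

    def test_pure_noise_mean_r2_near_one_over_n_minus_one(self):
        rng = np.random.default_rng(8)
        n = 200
        y = rng.normal(size=n)
        X = rng.normal(size=(n, 4, 50))
        scan = ep.single_df_scan(y, X)
        assert np.nanmean(scan.r2) == pytest.approx(1 / (n - 1), rel=0.5)

    def test_constant_predictor_is_missing(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=25)
        X = np.ones((25, 1, 2))
        X[:, 0, 1] = rng.normal(size=25)
        scan = ep.single_df_scan(y, X)
        assert np.isnan(scan.r2[0, 0]) and np.isfinite(scan.r2[0, 1])

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ValueError, match="20"):
            ep.single_df_scan(np.zeros(10), np.zeros((10, 1, 1)))


class TestClassMaxR2:
    def test_max_dominates_every_cell_and_single_cell_is_its_own_max(self):
        rng = np.random.default_rng(10)
        r2 = rng.uniform(size=(3, 5))
        scan = ScanResult(beta=r2, r2=r2, n=30)
        table = class_max_r2({"t1": {"state": scan}})
        assert table.loc["t1", "state"] == r2.max()
        single = ScanResult(beta=r2[:1, :1], r2=r2[:1, :1], n=30)
        assert class_max_r2({"t": {"c": single}}).loc["t", "c"] == r2[0, 0]

    def test_adding_positions_never_decreases_max(self):
        rng = np.random.default_rng(11)
        r2 = rng.uniform(size=(2, 6))
        small = ScanResult(beta=r2[:, :3], r2=r2[:, :3], n=30)
        big = ScanResult(beta=r2, r2=r2, n=30)
        assert class_max_r2({"t": {"c": big}}).loc["t", "c"] >= \
            class_max_r2({"t": {"c": small}}).loc["t", "c"]


class TestEmpiricalPvalue:
    def test_counting_rule(self):
        perms = np.r_[np.full(10, 0.6), np.full(990, 0.1)]
        assert ep.empirical_pvalue(0.5, perms) == 0.01

    def test_observed_below_all_permutations(self):
        assert ep.empirical_pvalue(0.0, np.full(100, 0.5)) == 1.0

    def test_observed_above_all_permutations_is_zero_and_flagged(self):
        null = permutation_null(np.random.default_rng(0).normal(size=(4, 1, 3)),
                                np.random.default_rng(1).dirichlet(np.ones(4), 30),
                                np.random.default_rng(2).normal(size=30),
                                n_perm=5, seed=0)
        assert ep.empirical_pvalue(1.0, null.permuted_r2) == 0.0
        null.observed_r2 = 1.0
        assert null.below_resolution

    def test_ties_meet_the_threshold(self):
        assert ep.empirical_pvalue(0.5, np.full(10, 0.5)) == 1.0


class TestPermutationNull:
    def test_identity_permutation_reproduces_observed(self):
        rng = np.random.default_rng(12)
        founder = rng.normal(size=(8, 2, 4))
        haps = rng.dirichlet(np.ones(8), size=40)
        y = rng.normal(size=40)
        obs = ep.single_df_scan(y, ep.impute_feature(haps, founder)).max_r2()
        ident = ep.single_df_scan(
            y, ep.impute_feature(haps, founder[np.arange(8)])).max_r2()
        assert obs == ident

    def test_constant_founder_feature_is_permutation_invariant(self):
        rng = np.random.default_rng(13)
        founder = np.tile(rng.normal(size=(1, 2, 4)), (8, 1, 1))
        haps = rng.dirichlet(np.ones(8), size=40)
        y = rng.normal(size=40)
        null = permutation_null(founder, haps, y, n_perm=20, seed=3)
        assert np.allclose(null.permuted_r2, null.permuted_r2[0], equal_nan=True)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(14)
        founder = rng.normal(size=(8, 2, 4))
        haps = rng.dirichlet(np.ones(8), size=40)
        y = rng.normal(size=40)
        a = permutation_null(founder, haps, y, n_perm=15, seed=9)
        b = permutation_null(founder, haps, y, n_perm=15, seed=9)
        assert (a.permuted_r2 == b.permuted_r2).all()

    def test_transcript_streams_are_order_independent(self):
        a = transcript_rng(5, "geneA").integers(0, 1 << 30, 4)
        b = transcript_rng(5, "geneB").integers(0, 1 << 30, 4)
        a2 = transcript_rng(5, "geneA").integers(0, 1 << 30, 4)
        assert (a == a2).all() and not (a == b).all()


class TestUniformityCheck:
    def test_uniform_pvalues_pass(self):
        rng = np.random.default_rng(15)
        rep = uniformity_check(rng.uniform(size=500))
        assert rep.ks_pvalue > 0.01 and not rep.rejects()

    def test_degenerate_pvalues_reject_both_tests(self):
        rep = uniformity_check(np.full(100, 0.001))
        assert rep.ks_pvalue < 1e-6 and rep.kruskal_pvalue < 1e-6

    def test_signal_enriches_small_pvalues(self, do_panel):
        panel, do = do_panel
        pv = ep.permutation_pvalues(panel, do, feature="state", n_perm=50,
                                    seed=2)
        p = pv["pvalue"].dropna()
        # every gene carries the causal state: p-values should crowd low
        assert p.median() <= 0.1

    def test_too_few_pvalues_rejected(self):
        with pytest.raises(ValueError):
            uniformity_check(np.linspace(0, 1, 10))


class TestGeneReport:
    def test_flagged_region_contains_causal_position(self, do_panel):
        panel, do = do_panel
        gid = panel.genes["gene_id"].iloc[0]
        rep = ep.build_gene_report(panel, do, gid)
        causal = do.truth.do_causal_position[gid]
        ci = np.argmin(np.abs(rep.positions - causal))
        assert rep.flagged[ci]

    def test_report_is_deterministic(self, do_panel):
        panel, do = do_panel
        gid = panel.genes["gene_id"].iloc[1]
        r1 = ep.build_gene_report(panel, do, gid)
        r2 = ep.build_gene_report(panel, do, gid)
        pd.testing.assert_frame_equal(r1.r2_by_class, r2.r2_by_class)
        assert (r1.flagged == r2.flagged).all()

    def test_gene_without_snps_still_reports(self, do_panel):
        panel, do = do_panel
        gid = panel.genes["gene_id"].iloc[2]
        scans = ep.scan_gene(panel, do, gid, classes=("haplotype", "state"))
        _, positions, _ = ep.founder_feature_array(panel, gid, "state",
                                                   founders=do.founders)
        rep = ep.gene_report(gid, scans, positions, founder_snps=None)
        assert rep.r2_by_class.shape[0] == len(positions)
        assert any("SNP" in w for w in rep.warnings)
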