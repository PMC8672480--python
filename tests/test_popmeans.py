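"""Population mean layer: base means, variances, normalization, effects."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import scpopsim as sp
from scpopsim.popmeans import _bin_of


def two_bin_pop(s_v=1.0):
    return sp.PopParams(mean_shape=2.0, mean_rate=1.0, n_bins=2,
                        bin_edges=[0.0, 2.0, np.inf],
                        cv_shape_per_bin=[4.0, 12.0],
                        cv_rate_per_bin=[8.0, 60.0],
                        similarity_scale=s_v)


class TestSampleBaseMeans:
    def test_no_outliers_when_probability_zero(self, default_ps):
        sc = sp.SCParams(out_prob=0.0)
        _, flags, factors = sp.sample_base_means(default_ps.pop, sc, 1000, 1)
        assert not flags.any() and (factors == 1).all()

    def test_gamma_moments(self):
        pop = two_bin_pop()
        means, _, _ = sp.sample_base_means(pop, sp.SCParams(out_prob=0.0),
                                           100_000, 2)
        se = np.sqrt(2.0 / 100_000)  # var of gamma(2,1) is 2
        assert abs(means.mean() - 2.0) < 3 * se

    def test_forced_outlier_factor_one_pins_to_median(self):
        sc = sp.SCParams(out_prob=1.0, out_loc=0.0, out_scale=0.0)
        means, flags, factors = sp.sample_base_means(two_bin_pop(), sc, 101, 3)
        assert flags.all() and (factors == 1).all()
        assert np.allclose(means, np.median(means))


class TestSampleVariances:
    def test_bins_draw_from_their_own_gamma(self):
        pop = two_bin_pop()
        lam = np.array([1.0] * 10_000 + [5.0] * 10_000)
        sig = sp.sample_variances(lam, pop, seed=4)
        low, high = sig[:10_000], sig[10_000:]
        assert stats.kstest(low, stats.gamma(4.0, scale=1 / 8.0).cdf).pvalue > 0.01
        assert stats.kstest(high, stats.gamma(12.0, scale=1 / 60.0).cdf).pvalue > 0.01

    def test_similarity_scale_divides_the_cv(self):
        lam = np.full(20_000, 1.0)
        s1 = sp.sample_variances(lam, two_bin_pop(1.0), seed=5)
        s50 = sp.sample_variances(lam, two_bin_pop(50.0), seed=5)
        assert np.allclose(s50, s1 / 50.0)

    def test_out_of_range_means_use_nearest_bin(self):
        pop = two_bin_pop()
        assert _bin_of(np.array([1e-12, 1e12]), pop).tolist() == [0, 1]


class TestSampleIndividualMeans:
    def test_zero_cv_is_exact(self):
        out = sp.sample_individual_means(np.array([3.0, 7.0]),
                                         np.zeros(2), ["a", "b", "c"], 6)
        assert (out.to_numpy() == [[3.0] * 3, [7.0] * 3]).all()

    def test_cv_is_interpreted_as_sd_over_mean(self):
        out = sp.sample_individual_means(np.array([10.0]), np.array([0.5]),
                                         [f"i{j}" for j in range(10_000)], 7)
        sd = out.to_numpy().std()
        assert sd == pytest.approx(5.0, rel=0.05)

    def test_negative_draws_floored(self):
        out = sp.sample_individual_means(np.array([0.1]), np.array([50.0]),
                                         [f"i{j}" for j in range(1000)], 8)
        assert (out.to_numpy() >= 0).all()


class TestQuantileNormalize:
    def test_columns_match_target_gamma(self, rng):
        sc = sp.SCParams(mean_shape=0.6, mean_rate=0.3)
        raw = pd.DataFrame(rng.lognormal(2, 1, size=(800, 4)))
        out = sp.quantile_normalize(raw, sc)
        for j in range(4):
            p = stats.kstest(out.iloc[:, j],
                             stats.gamma(0.6, scale=1 / 0.3).cdf).pvalue
            assert p > 0.01

    def test_gamma_quantiles_are_a_fixed_point_up_to_order(self, rng):
        sc = sp.SCParams(mean_shape=2.0, mean_rate=1.0)
        n = 300
        q = stats.gamma.ppf((np.arange(1, n + 1) - 0.5) / n, 2.0, scale=1.0)
        col = rng.permutation(q)
        out = sp.quantile_normalize(col[:, None], sc)
        np.testing.assert_allclose(np.sort(out.ravel()), q)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.1, 1e4), min_size=5, max_size=60))
    def test_order_preserved_within_column(self, values):
        sc = sp.SCParams(mean_shape=0.6, mean_rate=0.3)
        col = np.asarray(values)[:, None]
        out = sp.quantile_normalize(col, sc).ravel()
        order = np.argsort(col.ravel(), kind="stable")
        assert (np.diff(out[order]) >= -1e-12).all()


class TestApplyEqtl:
    def setup_case(self, dosages, beta=0.5, specificity="global",
                   groups=("g1",), condition_of=None):
        inds = [f"i{j + 1}" for j in range(len(dosages))]
        means = pd.DataFrame({i: [10.0] for i in inds}, index=["geneA"])
        G = sp.GenotypeMatrix(snp_ids=["s1"], chrom=["1"], pos=[100],
                              dosage=np.array([dosages]), sample_ids=inds)
        key = [sp.EqtlAssignment(gene_id="geneA", snp_id="s1", beta=beta,
                                 specificity=specificity)]
        return sp.apply_eqtl(means, key, G, groups=groups,
                             condition_of=condition_of)

    def test_printed_formula_hand_values(self):
        pm = self.setup_case([0, 1, 2])
        np.testing.assert_allclose(pm.values[0, :, 0], [10.0, 15.0, 20.0])

    def test_zero_dosage_leaves_mean_unchanged(self):
        pm = self.setup_case([0, 0])
        np.testing.assert_allclose(pm.values[0, :, 0], 10.0)

    def test_group_specific_touches_only_target_slice(self):
        pm = self.setup_case([2, 2], specificity="group:g2",
                             groups=("g1", "g2"))
        np.testing.assert_allclose(pm.values[0, :, 0], 10.0)
        np.testing.assert_allclose(pm.values[0, :, 1], 20.0)

    def test_condition_specific_touches_only_cohort(self):
        pm = self.setup_case([2, 2], specificity="condition:c2",
                             condition_of={"i1": "c1", "i2": "c2"})
        np.testing.assert_allclose(pm.values[0, :, 0], [10.0, 20.0])

    def test_missing_esnp_is_named(self):
        means = pd.DataFrame({"i1": [1.0], "i2": [1.0]}, index=["geneA"])
        G = sp.GenotypeMatrix(snp_ids=["s1"], chrom=["1"], pos=[1],
                              dosage=np.array([[0, 1]]),
                              sample_ids=["i1", "i2"])
        key = [sp.EqtlAssignment(gene_id="geneA", snp_id="sX", beta=1.0)]
        with pytest.raises(ValueError, match="sX"):
            sp.apply_eqtl(means, key, G)


class TestApplyDe:
    def make_pm(self, n_genes, inds, groups=("g1", "g2"),
                condition_of=None):
        means = pd.DataFrame(np.ones((n_genes, len(inds))),
                             index=[f"g{i}" for i in range(n_genes)],
                             columns=inds)
        cond = condition_of or {i: "c1" for i in inds}
        from scpopsim.popmeans import _as_popmeans

        return _as_popmeans(means, groups, cond)

    def test_zero_probability_is_identity(self):
        pm = self.make_pm(100, ["i1", "i2"])
        before = pm.values.copy()
        out, de, cde = sp.apply_de(pm, sp.DEParams(de_prob=0.0, cde_prob=0.0),
                                   seed=1)
        np.testing.assert_array_equal(out.values, before)
        assert (de.to_numpy() == 1.0).all()

    def test_degenerate_lognormal_gives_unit_factors(self):
        pm = self.make_pm(200, ["i1", "i2"])
        _, de, _ = sp.apply_de(pm, sp.DEParams(de_prob=1.0, de_loc=0.0,
                                               de_scale=0.0, de_down_prob=0.0),
                               seed=2)
        assert np.allclose(de.to_numpy(), 1.0)

    def test_de_fraction_matches_probability(self):
        pm = self.make_pm(10_000, ["i1", "i2"])
        _, de, _ = sp.apply_de(pm, sp.DEParams(de_prob=0.4, de_loc=0.5),
                               seed=3)
        frac = (de["g2"] != 1.0).mean()
        se = np.sqrt(0.4 * 0.6 / 10_000)
        assert abs(frac - 0.4) < 4 * se

    def test_condition_factors_multiply_only_member_columns(self):
        pm = self.make_pm(50, ["i1", "i2"], groups=("g1",),
                          condition_of={"i1": "c1", "i2": "c2"})
        out, _, cde = sp.apply_de(
            pm, sp.DEParams(de_prob=0.0, cde_prob=1.0, cde_loc=1.0,
                            cde_scale=0.0, cde_down_prob=0.0), seed=4)
        # c1 genes column i1 scaled by its factor, i2 by the c2 factor
        np.testing.assert_allclose(out.values[:, 0, 0],
                                   cde["c1"].to_numpy())
        np.testing.assert_allclose(out.values[:, 1, 0],
                                   cde["c2"].to_numpy())


class TestReplicationMode:
    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            sp.use_empirical_means(pd.DataFrame([[1.0, -0.1]]))

    def test_eqtl_request_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="scpopsim"):
            sp.use_empirical_means(pd.DataFrame([[1.0, 2.0]]),
                                   bulk_derived=False, eqtl_requested=True)
        assert any("compound" in r.message for r in caplog.records)

    def test_replicates_input_pattern_through_cell_simulation(self, rng):
        # With effects off, mean-aggregated counts must correlate strongly
        # with the empirical input across genes x individuals.
        emp = pd.DataFrame(rng.gamma(2.0, 10.0, size=(100, 4)),
                           index=[f"G{i}" for i in range(100)],
                           columns=["a", "b", "c", "d"])
        ps = sp.default_params().with_overrides({
            "pop.bulk_derived": False, "eqtl.eqtl_prob": 0.0,
            "design.n_individuals": 4, "design.cells_per_individual": 500,
            "sc.lib_scale": 0.0, "design.master_seed": 11})
        bundle = sp.simulate(ps, empirical_means=emp)
        assert bundle.gene_ids == list(emp.index)
        assert list(bundle.key.baseline_means.columns) == list(emp.columns)
        agg = sp.aggregate(bundle.counts,
                           bundle.cell_meta["individual"].to_numpy(),
                           method="mean", gene_ids=bundle.gene_ids)
        agg_v = agg.values[list(emp.columns)].to_numpy()
        r = np.corrcoef(agg_v.ravel(), emp.to_numpy().ravel())[0, 1]
        assert r > 0.95


class TestKeyAndRecreatability:
    def test_simkey_tsv_round_trip(self, smoke_bundle, tmp_path):
        smoke_bundle.key.to_tsv(tmp_path)
        back = sp.SimKey.from_tsv(tmp_path)
        pd.testing.assert_frame_equal(back.gene_key, smoke_bundle.key.gene_key,
                                      check_dtype=False)
        pd.testing.assert_frame_equal(back.baseline_means,
                                      smoke_bundle.key.baseline_means)
        pd.testing.assert_frame_equal(back.individual_key,
                                      smoke_bundle.key.individual_key)

    def test_same_seed_recreates_key_and_means(self, default_ps):
        ps = default_ps.with_overrides({
            "sc.n_genes": 200, "design.n_individuals": 5,
            "design.cells_per_individual": 20, "design.master_seed": 42})
        b1 = sp.simulate(ps, keep_intermediates=True)
        b2 = sp.simulate(ps, keep_intermediates=True)
        pd.testing.assert_frame_equal(b1.key.gene_key, b2.key.gene_key)
        np.testing.assert_array_equal(b1.intermediates["popmeans"].values,
                                      b2.intermediates["popmeans"].values)

    def test_coregulated_pairs_correlate_more_than_random_pairs(self):
        ps = sp.default_params().with_overrides({
            "sc.n_genes": 300, "design.n_individuals": 100,
            "design.cells_per_individual": 1, "eqtl.eqtl_prob": 0.8,
            "eqtl.coreg_prop": 0.4, "eqtl.dist_max": 2_000_000.0,
            "design.master_seed": 17})
        b = sp.simulate(ps, keep_intermediates=True, chrom_length=5_000_000)
        key = b.key.gene_key
        means = b.intermediates["popmeans"].values[:, :, 0]
        idx = {g: i for i, g in enumerate(key.index)}
        paired = key[key["coreg_partner"] != ""]
        seen, paired_r = set(), []
        for g, row in paired.iterrows():
            if g in seen:
                continue
            seen.update((g, row["coreg_partner"]))
            paired_r.append(np.corrcoef(means[idx[g]],
                                        means[idx[row["coreg_partner"]]])[0, 1])
        rng = np.random.default_rng(0)
        egenes = list(b.key.egenes)
        rand_r = []
        for _ in range(300):
            a, c = rng.choice(egenes, 2, replace=False)
            rand_r.append(np.corrcoef(means[idx[a]], means[idx[c]])[0, 1])
        assert np.mean(paired_r) > np.mean(rand_r)

    def test_similarity_scale_shrinks_between_individual_variance(self):
        def total_var(sv, seed):
            ps = sp.default_params().with_overrides({
                "sc.n_genes": 150, "design.n_individuals": 20,
                "design.cells_per_individual": 1, "eqtl.eqtl_prob": 0.0,
                "pop.similarity_scale": sv, "design.master_seed": seed})
            b = sp.simulate(ps, keep_intermediates=True)
            m = b.intermediates["popmeans"].values[:, :, 0]
            return np.median(np.var(m, axis=1) / np.maximum(
                np.mean(m, axis=1) ** 2, 1e-12))

        for seed in range(3):
            assert total_var(0.5, seed) > total_var(5.0, seed) \
                > total_var(50.0, seed)
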