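"""LASSO screening, cluster ANOVA tests, p-value aggregation, QTC calling."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from hitgwas import (aggregate_pvalues, build_hierarchy, call_qtcs,
                     cluster_test, deduplicate_markers, hierarchical_adjust,
                     lasso_screen, run_hit, run_split,
                     simulate_structured_genotypes, simulate_phenotype,
                     EffectDistribution)

from conftest import make_genotypes


class TestLassoScreen:
    def test_recovers_causal_support_noiseless(self, rng):
        X = rng.normal(size=(80, 30))
        y = X[:, 7]
        S = lasso_screen(X, y, seed=0)
        assert 7 in S

    def test_single_marker_panel(self, rng):
        x = rng.normal(size=(40, 1))
        y = 2.0 * x[:, 0] + 0.01 * rng.normal(size=40)
        S = lasso_screen(x, y, seed=0)
        assert list(S) == [0]

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(60, 40))
        y = X[:, 3] - X[:, 11] + rng.normal(size=60)
        S1 = lasso_screen(X, y, seed=42)
        S2 = lasso_screen(X, y, seed=42)
        np.testing.assert_array_equal(S1, S2)

    def test_constant_phenotype_errors(self, rng):
        with pytest.raises(ValueError, match="constant"):
            lasso_screen(rng.normal(size=(40, 5)), np.ones(40))

    def test_single_class_binomial_errors(self, rng):
        with pytest.raises(ValueError, match="single class"):
            lasso_screen(rng.normal(size=(40, 5)), np.zeros(40), family="binomial")

    def test_binomial_screen_finds_strong_marker(self, rng):
        X = rng.normal(size=(120, 20))
        logit = 3.0 * X[:, 4]
        y = (rng.random(120) < 1 / (1 + np.exp(-logit))).astype(float)
        S = lasso_screen(X, y, family="binomial", seed=0)
        assert 4 in S

    def test_too_few_individuals_errors(self, rng):
        with pytest.raises(ValueError, match="screening half"):
            lasso_screen(rng.normal(size=(10, 5)), rng.normal(size=10))


class TestClusterTest:
    def test_full_cluster_equals_overall_f_test(self, rng):
        """members = S reduces to the regression F-test against the
        intercept-only model (statsmodels oracle, 10 x 3 toy)."""
        X = rng.normal(size=(10, 3))
        y = X @ np.array([1.0, 0.5, 0.0]) + rng.normal(size=10)
        p_ours = cluster_test(X, y, "gaussian", [0, 1, 2], [0, 1, 2])
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        assert p_ours == pytest.approx(fit.f_pvalue, rel=1e-10)

    def test_partial_f_matches_statsmodels_nested_comparison(self, rng):
        X = rng.normal(size=(40, 5))
        y = X @ np.array([1.0, -1.0, 0.3, 0.0, 0.0]) + rng.normal(size=40)
        S = [0, 1, 2, 3, 4]
        members = [1, 3]
        p_ours = cluster_test(X, y, "gaussian", members, S)
        full = sm.OLS(y, sm.add_constant(X)).fit()
        red = sm.OLS(y, sm.add_constant(X[:, [0, 2, 4]])).fit()
        _, p_sm, _ = full.compare_f_test(red)
        assert p_ours == pytest.approx(p_sm, rel=1e-8)

    def test_null_pvalues_are_uniform(self):
        """With a zero true coefficient the partial-F p-value is
        Uniform(0,1) (Kolmogorov-Smirnov over repeated simulation)."""
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(200):
            X = rng.normal(size=(500, 4))
            y = X[:, 0] + rng.normal(size=500)   # markers 1..3 are null
            pvals.append(cluster_test(X, y, "gaussian", [2], [0, 1, 2, 3]))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_signal_dominant_limit(self, rng):
        X = rng.normal(size=(200, 3))
        y = X[:, 1]                              # noiseless causal marker
        p = cluster_test(X, y, "gaussian", [1], [0, 1, 2])
        assert p < 1e-6

    def test_collinear_member_dropped_with_df_adjustment(self, rng):
        X = rng.normal(size=(30, 3))
        X = np.column_stack([X, X[:, 0]])        # column 3 duplicates 0
        y = X[:, 0] + rng.normal(size=30)
        # cluster {3} adds nothing beyond {0,1,2} -> p = 1
        assert cluster_test(X, y, "gaussian", [3], [0, 1, 2, 3]) == 1.0

    def test_binomial_likelihood_ratio_matches_logit_oracle(self, rng):
        X = rng.normal(size=(150, 3))
        logit = X[:, 0] - 0.5 * X[:, 2]
        y = (rng.random(150) < 1 / (1 + np.exp(-logit))).astype(float)
        p_ours = cluster_test(X, y, "binomial", [0], [0, 1, 2])
        full = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        red = sm.Logit(y, sm.add_constant(X[:, 1:])).fit(disp=0)
        lr = 2 * (full.llf - red.llf)
        assert p_ours == pytest.approx(stats.chi2.sf(lr, 1), rel=1e-5)

    def test_members_outside_selection_rejected(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        with pytest.raises(ValueError, match="subset"):
            cluster_test(X, y, "gaussian", [3], [0, 1])

    def test_saturated_design_errors(self, rng):
        X = rng.normal(size=(5, 10))
        y = rng.normal(size=5)
        with pytest.raises(ValueError, match="degrees of freedom"):
            cluster_test(X, y, "gaussian", [0], list(range(10)))


class TestHierarchicalAdjust:
    def test_root_with_all_selected_is_unchanged(self):
        assert hierarchical_adjust(0.03, 5, 5, 0.0) == pytest.approx(0.03)

    def test_selection_proportion_factor(self):
        assert hierarchical_adjust(0.01, 2, 4, 0.0) == pytest.approx(0.02)

    def test_capped_at_one(self):
        assert hierarchical_adjust(0.9, 1, 4, 0.0) == 1.0

    def test_monotonized_against_parent(self):
        assert hierarchical_adjust(0.001, 1, 1, 0.7) == 0.7

    def test_invalid_hits_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_adjust(0.5, 0, 4, 0.0)
        with pytest.raises(ValueError):
            hierarchical_adjust(0.5, 5, 4, 0.0)


class TestAggregatePValues:
    def test_all_ones(self):
        assert aggregate_pvalues([1.0] * 10) == 1.0

    def test_all_zeros(self):
        assert aggregate_pvalues([0.0] * 10) == 0.0

    def test_constant_small_pvalues_hand_evaluation(self):
        """B=50, all p=0.001: the infimum sits at gamma=1, so the
        aggregate is (1 - ln 0.05) * 0.001."""
        agg = aggregate_pvalues([0.001] * 50, gamma_min=0.05)
        assert agg == pytest.approx((1 - np.log(0.05)) * 0.001, rel=1e-12)
        assert agg == pytest.approx(0.0039957, abs=5e-7)

    def test_single_split_scaling(self):
        p = 0.004
        assert aggregate_pvalues([p], gamma_min=0.05) == pytest.approx(
            min(1.0, (1 - np.log(0.05)) * p))

    def test_matches_dense_gamma_grid(self, rng):
        """Order-statistic evaluation equals a dense numeric grid."""
        p = rng.random(37)
        B = len(p)
        gammas = np.linspace(0.05, 1.0, 20001)
        qs = [min(1.0, np.sort(p / g)[int(np.ceil(g * B)) - 1]) for g in gammas]
        dense = min(1.0, (1 - np.log(0.05)) * min(qs))
        assert aggregate_pvalues(p) == pytest.approx(dense, abs=1e-6)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            aggregate_pvalues([])
        with pytest.raises(ValueError):
            aggregate_pvalues([0.5, 1.2])


def _signal_setup(rng, n=120, p=40, n_causal=1, h2=0.95):
    G = simulate_structured_genotypes(n, p, 1, 0.0, seed=int(rng.integers(2**30)))
    ph, truth = simulate_phenotype(G, n_causal, EffectDistribution("gamma"), h2,
                                   seed=int(rng.integers(2**30)))
    Gd, dup = deduplicate_markers(G)
    H = build_hierarchy(Gd)
    return G, Gd, dup, H, ph, truth


class TestRunSplit:
    def test_split_halves_are_disjoint_and_cover(self, rng):
        G, Gd, dup, H, ph, truth = _signal_setup(rng)
        res = run_split(Gd, ph.values, H, seed=3)
        both = np.concatenate([res.screening_idx, res.testing_idx])
        assert len(np.intersect1d(res.screening_idx, res.testing_idx)) == 0
        assert sorted(both.tolist()) == list(range(Gd.n_individuals))

    def test_adjusted_pvalues_monotone_down_the_tree(self, rng):
        G, Gd, dup, H, ph, truth = _signal_setup(rng)
        res = run_split(Gd, ph.values, H, seed=1)
        for nd, p in res.node_pvalues.items():
            par = H.parent[nd]
            if par != -1 and par in res.node_pvalues:
                assert p >= res.node_pvalues[par] - 1e-12

    def test_strong_causal_marker_significant_to_its_leaf(self, rng):
        G, Gd, dup, H, ph, truth = _signal_setup(rng, h2=0.99)
        causal_id = G.marker_ids[truth.causal_indices[0]]
        leaf = Gd.marker_ids.index(causal_id)
        res = run_split(Gd, ph.values, H, seed=2)
        assert leaf in res.node_pvalues and res.node_pvalues[leaf] <= 0.05
        # every ancestor of the leaf was tested and significant
        nd = H.parent[leaf]
        while nd != -1:
            assert res.node_pvalues[nd] <= 0.05
            nd = H.parent[nd]

    def test_empty_selection_yields_no_tested_nodes(self, rng, monkeypatch):
        G, Gd, dup, H, ph, truth = _signal_setup(rng)
        import hitgwas.hit as hit_mod

        monkeypatch.setattr(
            hit_mod, "lasso_screen",
            lambda *a, **k: (np.array([], dtype=int), np.array([])))
        res = run_split(Gd, ph.values, H, seed=0)
        assert res.node_pvalues == {} and len(res.selected) == 0

    def test_too_few_individuals_errors(self, rng):
        G = make_genotypes(rng.normal(size=(10, 5)))
        H = build_hierarchy(G)
        with pytest.raises(ValueError, match="20 individuals"):
            run_split(G, np.arange(10.0), H, seed=0)


class TestBinomialPath:
    def test_case_control_run_finds_strong_locus(self, rng):
        from hitgwas import simulate_binary_phenotype

        G = simulate_structured_genotypes(200, 40, 1, 0.0, seed=41)
        ph_cont, truth = simulate_phenotype(G, 1, h2=0.9, seed=42)
        ph = simulate_binary_phenotype(G, truth, prevalence=0.5, seed=43)
        Gd, dup = deduplicate_markers(G)
        H = build_hierarchy(Gd)
        table = run_hit(Gd, ph, H, family="binomial", n_splits=3, cv_folds=5,
                        seed=44)
        res = call_qtcs(table, H, Gd, dup)
        causal_id = G.marker_ids[truth.causal_indices[0]]
        assert any(causal_id in q.marker_ids for q in res.qtcs)


class TestRunHit:
    def test_bit_identical_under_same_seed(self, rng):
        G, Gd, dup, H, ph, truth = _signal_setup(rng)
        t1 = run_hit(Gd, ph, H, n_splits=4, seed=11)
        t2 = run_hit(Gd, ph, H, n_splits=4, seed=11)
        assert t1.node_pvalues == t2.node_pvalues
        np.testing.assert_array_equal(t1.selection_freq, t2.selection_freq)

    def test_parallel_execution_matches_serial(self, rng):
        G, Gd, dup, H, ph, truth = _signal_setup(rng, n=60, p=20)
        t1 = run_hit(Gd, ph, H, n_splits=3, seed=7, n_jobs=1)
        t2 = run_hit(Gd, ph, H, n_splits=3, seed=7, n_jobs=2)
        assert t1.node_pvalues == t2.node_pvalues

    def test_single_split_table_is_scaled_split_table(self, rng):
        G, Gd, dup, H, ph, truth = _signal_setup(rng)
        table = run_hit(Gd, ph, H, n_splits=1, seed=9)
        split = table.splits[0]
        scale = 1 - np.log(table.gamma_min)
        for nd, p_agg in table.node_pvalues.items():
            expected = min(1.0, scale * split.node_pvalues[nd])
            par = H.parent[nd]
            if par != -1 and par in table.node_pvalues:
                expected = max(expected, table.node_pvalues[par])
            assert p_agg == pytest.approx(expected)

    def test_aggregated_pvalues_monotone(self, rng):
        G, Gd, dup, H, ph, truth = _signal_setup(rng)
        table = run_hit(Gd, ph, H, n_splits=4, seed=13)
        for nd, p in table.node_pvalues.items():
            par = H.parent[nd]
            if par != -1 and par in table.node_pvalues:
                assert p >= table.node_pvalues[par] - 1e-12

    def test_fixed_covariate_absorbed_in_screening_and_testing(self, rng):
        """A strong sex-like covariate neither masks a causal marker nor
        creates spurious findings when modeled as a fixed covariate."""
        G, Gd, dup, H, ph, truth = _signal_setup(rng, n=200, p=30, h2=0.8)
        sex = (np.arange(200) % 2).astype(float)[:, None]
        y = ph.values + 5.0 * sex.ravel()
        table = run_hit(Gd, y, H, n_splits=5, seed=37, covariates=sex)
        causal_id = G.marker_ids[truth.causal_indices[0]]
        leaf = Gd.marker_ids.index(causal_id)
        assert table.node_pvalues.get(leaf, 1.0) <= 0.05

    def test_selection_frequency_definition(self, rng):
        G, Gd, dup, H, ph, truth = _signal_setup(rng)
        table = run_hit(Gd, ph, H, n_splits=5, seed=17)
        counts = np.zeros(Gd.p_markers)
        for s in table.splits:
            counts[s.selected] += 1
        np.testing.assert_allclose(table.selection_freq, counts / 5)


class TestCallQtcs:
    def test_no_significant_nodes_gives_empty_result(self, rng):
        G, Gd, dup, H, ph, truth = _signal_setup(rng)
        table = run_hit(Gd, ph, H, n_splits=3, seed=19)
        table.node_pvalues = {nd: 1.0 for nd in table.node_pvalues}
        assert call_qtcs(table, H, Gd, dup).qtcs == []

    def test_minimality_against_brute_force_scan(self, rng):
        G, Gd, dup, H, ph, truth = _signal_setup(rng, h2=0.95)
        table = run_hit(Gd, ph, H, n_splits=5, seed=23)
        res = call_qtcs(table, H, Gd, dup)
        sig = {nd for nd, p in table.node_pvalues.items() if p <= 0.05}

        def has_sig_descendant(nd):
            return any(k in sig or has_sig_descendant(k) for k in H.children[nd])

        expected = {nd for nd in sig
                    if not has_sig_descendant(nd) and H.height[nd] <= 0.5}
        assert {q.node_id for q in res.qtcs} == expected
        # reported QTCs are pairwise disjoint and significant
        seen = set()
        for q in res.qtcs:
            ms = set(H.members[q.node_id].tolist())
            assert not (ms & seen)
            seen |= ms
            assert q.p_value <= 0.05

    def test_duplicates_reinstated_into_qtc(self, rng):
        n = 150
        causal = rng.binomial(2, 0.5, size=n).astype(float)
        noise = [rng.binomial(2, 0.5, size=n).astype(float) for _ in range(6)]
        vals = np.column_stack([causal, causal, 2 - causal] + noise)
        G = make_genotypes(vals)
        y = 2.0 * causal + 0.1 * rng.normal(size=n)
        Gd, dup = deduplicate_markers(G)
        assert dup.n_collapsed() == 2
        H = build_hierarchy(Gd)
        table = run_hit(Gd, y, H, n_splits=5, seed=29)
        res = call_qtcs(table, H, Gd, dup)
        assert len(res.qtcs) == 1
        assert sorted(res.qtcs[0].marker_ids) == ["m0", "m1", "m2"]

    def test_diffuse_high_clusters_are_not_called(self, rng):
        """A significant node whose members are weakly correlated
        (height above the eligibility bound) is not a QTC."""
        G, Gd, dup, H, ph, truth = _signal_setup(rng)
        table = run_hit(Gd, ph, H, n_splits=3, seed=31)
        table.node_pvalues = {H.root: 1e-6}     # only a diffuse root signal
        if H.height[H.root] > 0.5:
            assert call_qtcs(table, H, Gd, dup).qtcs == []
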