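import numpy as np
import pandas as pd
import pytest

import pathwave as pw
from pathwave.stats import STATISTIC_CAP, GumbelNull, _child_seed


class TestFeatureStatistic:
    def test_constant_equal_groups_score_zero(self):
        s = pw.feature_statistic([1, 1, 1], [1, 1, 1])
        assert s.statistic == 0.0

    def test_zero_variance_separation_capped(self):
        s = pw.feature_statistic([0, 0], [1, 1])
        assert s.statistic == STATISTIC_CAP
        assert s.sign == -1  # mean(A) - mean(B) < 0

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            pw.feature_statistic([1], [1, 2])

    def test_matches_scipy_welch(self, rng):
        a, b = rng.normal(size=12), rng.normal(1, 2, size=9)
        from scipy import stats as sps

        expect = abs(sps.ttest_ind(a, b, equal_var=False).statistic)
        assert pw.feature_statistic(a, b).statistic == pytest.approx(expect, rel=1e-10)

    def test_monte_carlo_expectation(self):
        """For N(1,1) vs N(0,1) with n=50 each the expected |t| is about
        delta / sqrt(2/n) = 5."""
        rng = np.random.default_rng(2024)
        stats = [
            pw.feature_statistic(rng.normal(1, 1, 50), rng.normal(0, 1, 50)).statistic
            for _ in range(200)
        ]
        assert abs(np.mean(stats) - 5.0) < 0.5


class TestPathwayScore:
    def test_all_constant_features_score_zero(self):
        F = np.ones((6, 5))
        labels = np.array([True] * 3 + [False] * 3)
        score, best = pw.pathway_score(F, labels)
        assert score == 0.0

    def test_perfectly_separating_feature_selected(self, rng):
        F = rng.normal(size=(8, 10)) * 0.01
        labels = np.array([True] * 4 + [False] * 4)
        F[:, 7] = np.where(labels, 10.0, -10.0) + rng.normal(size=8) * 0.01
        score, best = pw.pathway_score(F, labels)
        assert best.index == 7 and best.sign == 1

    def test_tie_broken_by_canonical_order(self):
        labels = np.array([True, True, False, False])
        F = np.zeros((4, 3))
        F[:, 1] = [1, 1, 0, 0]
        F[:, 2] = [1, 1, 0, 0]
        _, best = pw.pathway_score(F, labels)
        assert best.index == 1


class TestPermutationNull:
    def _data(self, rng, n=20, f=30):
        F = rng.normal(size=(n, f))
        labels = np.array([True] * (n // 2) + [False] * (n // 2))
        return F, labels

    def test_identity_permutation_reproduces_observed_score(self, rng):
        F, labels = self._data(rng)
        score, _ = pw.pathway_score(F, labels)
        from pathwave.stats import _stat_matrix

        t, _ = _stat_matrix(F, labels[None, :].astype(float))
        assert t.max() == pytest.approx(score)

    def test_same_seed_bit_identical(self, rng):
        F, labels = self._data(rng)
        a = pw.permutation_null(F, labels, n_perm=200, seed=5)
        b = pw.permutation_null(F, labels, n_perm=200, seed=5)
        assert np.array_equal(a.scores, b.scores)
        assert (a.loc, a.scale) == (b.loc, b.scale)

    def test_too_few_permutations_rejected(self, rng):
        F, labels = self._data(rng)
        with pytest.raises(ValueError):
            pw.permutation_null(F, labels, n_perm=50)

    def test_degenerate_null_rejected(self):
        F = np.ones((8, 3))
        labels = np.array([True] * 4 + [False] * 4)
        with pytest.raises(ValueError, match="degenerate"):
            pw.permutation_null(F, labels, n_perm=100)

    def test_class_sizes_preserved(self, rng):
        from pathwave.stats import _permutation_matrix

        labels = np.array([True] * 7 + [False] * 13)
        P = _permutation_matrix(labels, 50, rng)
        assert (P.sum(axis=1) == 7).all()

    def test_paired_permutation_swaps_within_pairs(self, rng):
        from pathwave.stats import _permutation_matrix

        labels = np.array([True, False] * 5)
        pairs = np.repeat([f"p{i}" for i in range(5)], 2)
        P = _permutation_matrix(labels, 40, rng, pairs=pairs)
        assert (P.sum(axis=1) == 5).all()
        for row in P:
            for k in range(5):
                assert row[2 * k] + row[2 * k + 1] == 1


class TestGumbelPvalue:
    def test_closed_forms(self):
        null = GumbelNull(loc=2.0, scale=0.5, n_permutations=100, scores=np.arange(100.0))
        assert pw.gumbel_pvalue(2.0, null) == pytest.approx(1 - np.exp(-1), abs=1e-12)
        median = 2.0 - 0.5 * np.log(np.log(2))
        assert pw.gumbel_pvalue(median, null) == pytest.approx(0.5, abs=1e-12)

    def test_monotone_decreasing_and_clamped(self):
        null = GumbelNull(loc=0.0, scale=1.0, n_permutations=100, scores=np.arange(100.0))
        ps = [pw.gumbel_pvalue(s, null) for s in np.linspace(-5, 50, 40)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert pw.gumbel_pvalue(1e9, null) >= np.finfo(float).tiny

    def test_invalid_scale(self):
        with pytest.raises(ValueError):
            GumbelNull(loc=0.0, scale=0.0, n_permutations=100, scores=np.zeros(100))


class TestAdjustPvalues:
    def test_bonferroni_hand_values(self):
        p = [0.001] + [0.5] * 49
        out = pw.adjust_pvalues(p, "bonferroni")
        assert out[0] == pytest.approx(0.05)
        assert out[1] == 1.0  # capped

    def test_single_test_unchanged(self):
        for method in ("bonferroni", "holm", "BH"):
            assert pw.adjust_pvalues([0.3], method)[0] == pytest.approx(0.3)

    def test_holm_and_bh_against_manual_definitions(self, rng):
        p = rng.uniform(size=12)
        m = len(p)
        order = np.argsort(p)
        # Holm: step-down max of (m - k) * p_(k), capped
        holm = np.empty(m)
        running = 0.0
        for k, idx in enumerate(order):
            running = max(running, (m - k) * p[idx])
            holm[idx] = min(running, 1.0)
        # BH: step-up min of m/k * p_(k)
        bh = np.empty(m)
        running = 1.0
        for k in range(m - 1, -1, -1):
            running = min(running, m / (k + 1) * p[order[k]])
            bh[order[k]] = running
        assert np.allclose(pw.adjust_pvalues(p, "holm"), holm)
        assert np.allclose(pw.adjust_pvalues(p, "BH"), bh)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pw.adjust_pvalues([1.5], "bonferroni")

    def test_order_preserving(self, rng):
        p = rng.uniform(size=20)
        for method in ("bonferroni", "holm", "BH"):
            adj = pw.adjust_pvalues(p, method)
            assert ((np.sign(np.subtract.outer(p, p)) *
                     np.sign(np.subtract.outer(adj, adj))) >= 0).all()


class TestCountUpDown:
    def _frame(self, arr, nodes=None):
        arr = np.asarray(arr, float)
        nodes = nodes or [f"R{i}" for i in range(arr.shape[0])]
        return pd.DataFrame(arr, index=nodes,
                            columns=[f"s{j}" for j in range(arr.shape[1])])

    def test_counts_sum_to_measured(self, rng):
        arr = rng.normal(size=(12, 16))
        arr[3, :] = np.nan  # unmeasured
        labels = np.array([True] * 8 + [False] * 8)
        up, nc, down, calls = pw.count_up_down(self._frame(arr), labels)
        assert up + nc + down == 11 == len(calls)

    def test_strong_shift_counted_up(self, rng):
        arr = rng.normal(size=(5, 40))
        labels = np.array([True] * 20 + [False] * 20)
        arr[2, labels] += 5.0
        up, nc, down, calls = pw.count_up_down(self._frame(arr), labels)
        assert calls["R2"] == "up" and up >= 1

    def test_null_false_positive_rate_bounded(self, rng):
        arr = rng.normal(size=(100, 20))
        labels = np.array([True] * 10 + [False] * 10)
        up, nc, down, _ = pw.count_up_down(self._frame(arr), labels, alpha=0.05)
        # per-pathway Bonferroni over 100 reactions: expected false calls << 1
        assert up + down <= 3

    def test_paired_design_uses_signed_rank(self, rng):
        n = 12
        base = rng.normal(size=(3, n))
        arr = np.concatenate([base + 0.5, base], axis=1)  # A = B + 0.5 per pair
        labels = np.array([True] * n + [False] * n)
        pairs = np.concatenate([np.arange(n), np.arange(n)]).astype(str)
        up, nc, down, _ = pw.count_up_down(self._frame(arr), labels, pairs=pairs)
        assert up == 3 and down == 0


@pytest.fixture(scope="module")
def bench():
    spec = pw.FixtureSpec(n_pathways=4, nodes_min=6, nodes_max=8,
                          n_samples_per_class=6, delta=3.0, switch_size=3, seed=8)
    return pw.make_benchmark(spec, n_planted=1)


class TestRunAnalysis:
    def test_result_contract(self, bench):
        res = pw.run_analysis(bench.pathways, bench.expr, n_perm=200, seed=1)
        assert len(res.results) == 4
        for r in res.results:
            assert r.n_up + r.n_nochange + r.n_down == r.n_measured
            assert r.p_adjusted >= r.p_value
            assert 0 < r.p_value <= 1
        padj = [r.p_adjusted for r in res.results]
        assert padj == sorted(padj)

    def test_planted_pathway_ranks_first(self, bench):
        res = pw.run_analysis(bench.pathways, bench.expr, n_perm=300, seed=2)
        planted = next(pid for pid, v in bench.truth.items() if v)
        assert res.results[0].pathway_id == planted
        assert res.filtered and res.filtered[0].pathway_id == planted

    def test_min_dysregulated_filter(self, bench):
        res = pw.run_analysis(bench.pathways, bench.expr, n_perm=200, seed=1,
                              min_dysregulated=10)
        # pathways have at most 8 reactions, so none can satisfy the filter
        assert res.filtered == []

    def test_pathway_with_too_few_measured_reactions_skipped(self, bench, caplog):
        import copy

        pathways = [copy.deepcopy(p) for p in bench.pathways]
        starved = pathways[1]
        starved.network.node_genes = {v: frozenset() for v in starved.network.nodes}
        with caplog.at_level("WARNING"):
            res = pw.run_analysis(pathways, bench.expr, n_perm=200, seed=1)
        assert len(res.results) == 3
        assert "fewer than 2 measured" in caplog.text

    def test_child_seeds_independent_of_iteration_order(self, bench):
        fwd = pw.run_analysis(bench.pathways, bench.expr, n_perm=200, seed=4)
        rev = pw.run_analysis(bench.pathways[::-1], bench.expr, n_perm=200, seed=4)
        p_fwd = {r.pathway_id: r.p_value for r in fwd.results}
        p_rev = {r.pathway_id: r.p_value for r in rev.results}
        assert p_fwd == p_rev

    def test_seed_derivation_below_31_bits(self):
        rng = _child_seed(123, "some_pathway")
        assert isinstance(rng, np.random.Generator)
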