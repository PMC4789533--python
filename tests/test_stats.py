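"""Permutation testing, Spearman correlation, Holm-Bonferroni correction."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dticonn import (
    correlate_edges_with_scores,
    holm_bonferroni,
    make_cohort,
    permutation_group_test,
    spearman_rho,
    spearman_rho_pvalue,
)
from dticonn.synthetic import CohortSpec

from .conftest import one_edge_stack


def brute_force_average_ranks(v):
    v = np.asarray(v, dtype=float)
    r = np.empty(len(v))
    for k, x in enumerate(v):
        r[k] = np.sum(v < x) + (np.sum(v == x) + 1) / 2.0
    return r


def brute_force_spearman(x, y):
    rx = brute_force_average_ranks(x)
    ry = brute_force_average_ranks(y)
    dx, dy = rx - rx.mean(), ry - ry.mean()
    return float(np.sum(dx * dy) / np.sqrt(np.sum(dx * dx) * np.sum(dy * dy)))


def brute_force_exhaustive_p(values, n_a):
    """Two-sided exact permutation p for a single edge, all C(n, n_a) splits."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    obs = values[:n_a].mean() - values[n_a:].mean()
    count, total = 0, 0
    for combo in combinations(range(n), n_a):
        sel = np.zeros(n, dtype=bool)
        sel[list(combo)] = True
        t = values[sel].mean() - values[~sel].mean()
        count += abs(t) >= abs(obs) - 1e-12
        total += 1
    return count / total


class TestPermutationTest:
    def test_exhaustive_matches_hand_enumeration(self):
        stack = one_edge_stack([1, 2, 3, 10, 11, 12], ["A"] * 3 + ["B"] * 3)
        res = permutation_group_test(stack, method="exhaustive")
        assert res.p_uncorrected[0] == pytest.approx(2 / 20)  # only extreme splits
        assert res.observed_stat[0] == pytest.approx(-9.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_exhaustive_matches_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.integers(0, 30, 8).astype(float)
        vals[0] += 1  # keep the edge testable
        stack = one_edge_stack(vals, ["A"] * 4 + ["B"] * 4)
        res = permutation_group_test(stack, method="exhaustive")
        assert res.p_uncorrected[0] == pytest.approx(brute_force_exhaustive_p(vals, 4))

    def test_identical_subjects_give_null_stat_and_p_one(self):
        stack = one_edge_stack([7.0] * 8, ["A"] * 4 + ["B"] * 4)
        res = permutation_group_test(stack, n_permutations=500, seed=0)
        assert res.observed_stat[0] == 0.0
        assert res.p_uncorrected[0] == 1.0

    def test_seeded_runs_are_identical(self):
        stack, _ = make_cohort(CohortSpec(n_regions=8, seed=2))
        a = permutation_group_test(stack, n_permutations=2000, seed=5)
        b = permutation_group_test(stack, n_permutations=2000, seed=5)
        assert np.array_equal(a.p_uncorrected, b.p_uncorrected)
        assert np.array_equal(a.p_corrected, b.p_corrected)

    def test_corrected_p_dominates_uncorrected(self):
        stack, _ = make_cohort(CohortSpec(n_regions=8, seed=3))
        res = permutation_group_test(stack, n_permutations=1000, seed=1)
        assert np.all(res.p_corrected >= res.p_uncorrected - 1e-12)
        assert np.all((res.p_uncorrected > 0) & (res.p_uncorrected <= 1))

    def test_all_zero_edges_excluded_from_family(self):
        stack = one_edge_stack([0.0] * 8, ["A"] * 4 + ["B"] * 4)
        res = permutation_group_test(stack, n_permutations=100, seed=0)
        assert res.edges == []

    def test_input_validation(self):
        stack = one_edge_stack([1, 2, 3, 4, 5, 6], ["A"] * 3 + ["B"] * 3)
        with pytest.raises(ValueError, match="n_permutations"):
            permutation_group_test(stack, n_permutations=0)
        with pytest.raises(ValueError, match="at least 2"):
            one_edge_stack([1, 2, 3], ["A", "B", "B"])


class TestSpearman:
    def test_monotone_increasing_is_one(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)

    def test_monotone_decreasing_is_minus_one(self):
        assert spearman_rho([1, 2, 3, 4], [8, 6, 4, 2]) == pytest.approx(-1.0)

    def test_tied_input_matches_brute_force(self):
        x, y = [1, 2, 2, 4], [3, 1, 4, 4]
        assert spearman_rho(x, y) == pytest.approx(brute_force_spearman(x, y), abs=1e-12)

    def test_matches_scipy_reference(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.integers(0, 6, 12)
            y = rng.integers(0, 6, 12)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            rho, p = spearman_rho_pvalue(x, y)
            ref = spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        st.lists(st.integers(0, 8), min_size=4, max_size=12),
        st.floats(0.1, 5.0),
        st.floats(-10.0, 10.0),
    )
    def test_invariant_under_strictly_increasing_transform(self, y, a, b):
        x = np.arange(len(y), dtype=float)
        y = np.asarray(y, dtype=float)
        if np.all(y == y[0]):
            return
        base = spearman_rho(x, y)
        assert spearman_rho(a * x + b, y) == pytest.approx(base, abs=1e-9)
        assert spearman_rho(x ** 3 + 1, y) == pytest.approx(base, abs=1e-9)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])

    def test_short_or_mismatched_inputs_raise(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [3, 4])
        with pytest.raises(ValueError):
            spearman_rho([1, 2, 3], [1, 2])


class TestHolmBonferroni:
    def test_hand_computed_step_down(self):
        adj, rej = holm_bonferroni(np.array([0.001, 0.02, 0.04]), alpha=0.05)
        assert adj == pytest.approx([0.003, 0.04, 0.04])
        assert rej.all()

    def test_all_ones_rejects_nothing(self):
        adj, rej = holm_bonferroni(np.ones(3), alpha=0.05)
        assert np.all(adj == 1.0) and not rej.any()

    def test_single_p_unchanged(self):
        adj, rej = holm_bonferroni(np.array([0.03]), alpha=0.05)
        assert adj[0] == pytest.approx(0.03) and rej[0]

    def test_step_down_stops_at_first_failure(self):
        # second-smallest fails its step, so the larger (but nominally
        # significant-looking) third p must not be rejected either
        adj, rej = holm_bonferroni(np.array([0.001, 0.04, 0.045]), alpha=0.05)
        assert rej.tolist() == [True, False, False]

    def test_out_of_range_p_raises(self):
        with pytest.raises(ValueError):
            holm_bonferroni(np.array([0.1, 1.5]))
        with pytest.raises(ValueError):
            holm_bonferroni(np.array([-0.1, 0.5]))

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10), st.floats(0.01, 0.2))
    def test_matches_statsmodels_reference(self, p, alpha):
        from statsmodels.stats.multitest import multipletests

        p = np.asarray(p)
        adj, rej = holm_bonferroni(p, alpha=alpha)
        ref_rej, ref_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
        assert adj == pytest.approx(ref_adj, abs=1e-12)
        assert np.array_equal(rej, ref_rej)


class TestCorrelateEdges:
    def test_exact_monotone_link_survives_correction(self):
        stack, _ = make_cohort(CohortSpec(n_regions=5, n_group_a=10, n_group_b=10, seed=1))
        stack.scores = 2 * stack.matrices[:, 0, 1] + 1
        res = correlate_edges_with_scores(stack, [(0, 1), (2, 3)], alpha=0.001)
        assert (0, 1) in res.significant_edges
        assert res.rho[res.edges.index((0, 1))] == pytest.approx(1.0)

    def test_constant_edge_excluded(self):
        stack, _ = make_cohort(CohortSpec(n_regions=5, n_group_a=10, n_group_b=10, seed=1))
        stack.matrices[:, 0, 1] = 3
        stack.matrices[:, 1, 0] = 3
        res = correlate_edges_with_scores(stack, [(0, 1), (2, 3)])
        assert (0, 1) in res.excluded_edges
        assert (0, 1) not in res.edges

    def test_negative_slope_recovered_with_negative_sign(self):
        # decreased-in-group-B edge with a negative score link
        spec = CohortSpec(
            n_regions=6,
            baseline_mean=30.0,
            effect_edges=((1, 2, 0.4),),
            score_edges=((1, 2, -0.6),),
            score_baseline=25.0,
            seed=21,
        )
        stack, _ = make_cohort(spec)
        res = correlate_edges_with_scores(stack, [(1, 2)], alpha=0.01)
        assert res.rho[0] < -0.3
        assert res.significant_edges == [(1, 2)]

    def test_empty_edge_list_raises(self):
        stack, _ = make_cohort(CohortSpec(n_regions=4, seed=0))
        with pytest.raises(ValueError):
            correlate_edges_with_scores(stack, [])
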