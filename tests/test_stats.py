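"""Correlation, permutation-null, p-value and q-value tests.

Expected values come from independent oracles: a direct covariance/sigma
evaluation for Pearson's formula, exhaustive permutation enumeration for
small N, and a hand-applied Benjamini-Hochberg step-up for q-values with
pi0 fixed at 1.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from teharm import (
    MutationMatrix,
    MutationProfile,
    WindowGrid,
    build_mutation_matrix,
    compute_window_statistics,
    empirical_p_values,
    estimate_q_values,
    observed_correlations,
    pearson,
    permutation_null,
)


def pearson_oracle(x, y):
    """Direct evaluation of cov(X,Y)/(sigma_X sigma_Y), coded independently."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    sx = math.sqrt(sum((a - mx) ** 2 for a in x) / n)
    sy = math.sqrt(sum((b - my) ** 2 for b in y) / n)
    return cov / (sx * sy)


def matrix_from_columns(cols):
    cols = np.asarray(cols, dtype=int).T
    grid = WindowGrid(L=cols.shape[1], wsize=1)
    ids = tuple(f"e{i}" for i in range(cols.shape[0]))
    return MutationMatrix(values=cols, row_ids=ids, grid=grid)


class TestPearson:
    def test_perfect_positive(self):
        assert pearson([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_formula_oracle(self):
        x, y = [0, 1, 0, 2], [5, 1, 4, 0]
        assert pearson(x, y) == pytest.approx(pearson_oracle(x, y))

    def test_zero_variance_is_flagged_undefined(self):
        assert math.isnan(pearson([1, 1, 1], [1, 2, 3]))

    def test_length_mismatch_and_short_input(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson([1], [2])

    @given(
        xs=st.lists(st.integers(0, 20), min_size=3, max_size=12),
        a=st.floats(0.1, 5),
        b=st.floats(-10, 10),
        seed=st.integers(0, 999),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetry_and_affine_invariance(self, xs, a, b, seed):
        rng = np.random.default_rng(seed)
        ys = rng.normal(size=len(xs))
        x = np.array(xs, dtype=float)
        r = pearson(x, ys)
        if math.isnan(r):
            return
        assert pearson(ys, x) == pytest.approx(r)
        assert pearson(a * x + b, ys) == pytest.approx(r, abs=1e-9)
        assert pearson(-a * x + b, ys) == pytest.approx(-r, abs=1e-9)


class TestObservedCorrelations:
    def test_column_equal_to_activity(self):
        act = np.array([3.0, 1.0, 4.0, 2.0])
        M = matrix_from_columns([[3, 1, 4, 2], [0, 0, 1, 0]])
        rho = observed_correlations(M, act)
        assert rho[0] == pytest.approx(1.0)

    def test_zero_variance_column_flagged(self):
        M = matrix_from_columns([[0, 0, 0, 0], [1, 0, 2, 0]])
        rho = observed_correlations(M, [100.0, 60.0, 20.0, 0.0])
        assert math.isnan(rho[0]) and not math.isnan(rho[1])

    def test_matches_per_column_oracle(self):
        cols = [[0, 1, 0, 2], [1, 1, 0, 0], [2, 0, 1, 3]]
        act = [100.0, 60.0, 20.0, 0.0]
        rho = observed_correlations(matrix_from_columns(cols), act)
        for j, col in enumerate(cols):
            assert rho[j] == pytest.approx(pearson_oracle(col, act))

    def test_constant_activity_is_error(self):
        M = matrix_from_columns([[0, 1, 0, 2]])
        with pytest.raises(ValueError, match="constant"):
            observed_correlations(M, [5.0, 5.0, 5.0, 5.0])


class TestPermutationNull:
    def test_reproducible_given_seed(self):
        M = matrix_from_columns([[0, 1, 0, 2], [1, 1, 0, 0]])
        act = [100.0, 60.0, 20.0, 0.0]
        a = permutation_null(M, act, 50, seed=3)
        b = permutation_null(M, act, 50, seed=3)
        assert np.array_equal(a, b, equal_nan=True)

    def test_constant_column_yields_undefined_everywhere(self):
        M = matrix_from_columns([[2, 2, 2, 2], [0, 1, 0, 2]])
        null = permutation_null(M, [100.0, 60.0, 20.0, 0.0], 20, seed=0)
        assert np.isnan(null[:, 0]).all()
        assert not np.isnan(null[:, 1]).any()

    def test_monte_carlo_converges_to_exact_enumeration(self):
        """The empirical left-tail mass at the observed correlation converges
        to the value from enumerating all N! column permutations."""
        col = [0, 1, 0, 2]
        act = [100.0, 60.0, 20.0, 0.0]
        rho_obs = pearson_oracle(col, act)
        exact = np.mean(
            [
                pearson_oracle(perm, act) <= rho_obs + 1e-12
                for perm in itertools.permutations(col)
            ]
        )
        M = matrix_from_columns([col])
        n = 4000
        null = permutation_null(M, act, n, seed=11)
        mc = np.mean(null[:, 0] <= rho_obs + 1e-12)
        se = math.sqrt(exact * (1 - exact) / n)
        assert abs(mc - exact) <= 3 * se


class TestEmpiricalPValues:
    def test_direct_count_both_conventions(self):
        null = np.array([[-0.9], [-0.5], [0.1], [0.4]])
        assert empirical_p_values([-0.5], null)[0] == pytest.approx(3 / 5)
        assert empirical_p_values([-0.5], null, mode="raw")[0] == pytest.approx(0.5)

    def test_observed_below_all(self):
        null = np.array([[-0.2], [0.1], [0.5]])
        assert empirical_p_values([-0.9], null)[0] == pytest.approx(1 / 4)
        assert empirical_p_values([-0.9], null, mode="raw")[0] == 0.0

    def test_observed_above_all(self):
        null = np.array([[-0.2], [0.1], [0.5]])
        assert empirical_p_values([0.9], null)[0] == pytest.approx(1.0)
        assert empirical_p_values([0.9], null, mode="raw")[0] == pytest.approx(1.0)

    def test_undefined_windows_stay_nan(self):
        null = np.array([[-0.2, np.nan], [0.1, np.nan]])
        p = empirical_p_values([0.0, np.nan], null)
        assert not math.isnan(p[0]) and math.isnan(p[1])

    @given(
        n=st.integers(1, 200),
        seed=st.integers(0, 999),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_add_one_p_values_never_zero(self, n, seed):
        rng = np.random.default_rng(seed)
        null = rng.normal(size=(n, 3))
        obs = rng.normal(size=3)
        p = empirical_p_values(obs, null)
        assert np.all(p >= 1 / (n + 1)) and np.all(p <= 1.0)


class TestQValues:
    def test_all_ones(self):
        assert np.allclose(estimate_q_values(np.ones(5), pi0=1.0), 1.0)

    def test_bh_step_up_hand_example(self):
        """p = (.01,.02,.03,.5), pi0=1: BH gives (0.04, 0.04, 0.04, 0.5)."""
        q = estimate_q_values(np.array([0.01, 0.02, 0.03, 0.5]), pi0=1.0)
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.5])

    def test_single_p(self):
        assert estimate_q_values(np.array([0.2]), pi0=1.0)[0] == pytest.approx(0.2)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            estimate_q_values(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            estimate_q_values(np.array([0.5, 1.2]))

    def test_nan_entries_excluded_and_returned_nan(self):
        q = estimate_q_values(np.array([0.01, np.nan, 0.5]), pi0=1.0)
        assert math.isnan(q[1]) and not math.isnan(q[0])

    def test_matches_bh_reference_with_pi0_one(self):
        from scipy.stats import false_discovery_control

        rng = np.random.default_rng(4)
        p = rng.uniform(0.001, 1.0, size=200)
        assert estimate_q_values(p, pi0=1.0) == pytest.approx(
            false_discovery_control(p, method="bh")
        )

    @given(seed=st.integers(0, 999))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_in_p(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-4, 1.0, size=50)
        q = estimate_q_values(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all((q > 0) & (q <= 1))


class TestTypeIErrorCalibration:
    def test_null_p_values_roughly_uniform_on_disjoint_windows(self):
        """With activity independent of mutations, about 5% of disjoint
        windows reach p <= 0.05 (within 3 binomial SEs, averaged over
        replicates)."""
        rng = np.random.default_rng(99)
        wsize, L, N = 5, 100, 40
        grid = WindowGrid(L=L, wsize=wsize)
        fractions = []
        n_rep = 8
        for _ in range(n_rep):
            profiles = [
                MutationProfile(
                    f"e{k}",
                    tuple(
                        sorted(rng.choice(L, size=rng.integers(2, 12), replace=False) + 1)
                    ),
                )
                for k in range(N)
            ]
            act = rng.uniform(0, 110, size=N)
            M = build_mutation_matrix(profiles, grid)
            stats = compute_window_statistics(
                M, act, n_perm=400, seed=int(rng.integers(2**31))
            )
            disjoint = np.arange(0, grid.nw, wsize)
            p = stats.p_values[disjoint]
            p = p[~np.isnan(p)]
            fractions.append(np.mean(p <= 0.05))
        n_eff = n_rep * len(disjoint)
        tol = 3 * math.sqrt(0.05 * 0.95 / n_eff)
        assert abs(np.mean(fractions) - 0.05) <= tol
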