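"""CP decomposition, signed-quartile discretization, fluidity metrics.

The metric implementation is checked against a brute-force oracle that
enumerates states and distances with explicit Python loops.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chronnectome as cn
from chronnectome.metastates import (
    ConnectivityPatterns,
    decompose_cps,
    discretize_quartiles,
    metastate_metrics,
    occupancy_fraction,
    possible_state_count,
    project_to_cps,
    sweep_dimensionality,
)


# ---------------------------------------------------------------- oracle


def metrics_bruteforce(D):
    """Loop-based meta-state metrics: the independent reference."""
    D = np.atleast_2d(np.asarray(D))
    states = [tuple(row) for row in D]
    distinct = []
    for s in states:
        if s not in distinct:
            distinct.append(s)
    n_changes = 0
    total = 0
    for a, b in zip(states[:-1], states[1:]):
        d = sum(abs(x - y) for x, y in zip(a, b))
        total += d
        if d > 0:
            n_changes += 1
    span = 0
    for i in range(len(distinct)):
        for j in range(i + 1, len(distinct)):
            d = sum(abs(x - y) for x, y in zip(distinct[i], distinct[j]))
            span = max(span, d)
    return len(distinct), n_changes, span, total


def random_trajectory(rng, W=None, k=None):
    W = W or rng.integers(1, 172)
    k = k or rng.integers(1, 9)
    vals = np.array([-4, -3, -2, -1, 1, 2, 3, 4])
    return vals[rng.integers(0, 8, size=(W, k))]


# ----------------------------------------------------------------- tests


class TestDecomposeCps:
    def test_recovers_planted_patterns(self, rng):
        # Hungarian matching against planted patterns in a constructed
        # mixture: rows are sparse nonnegative combinations of the CP
        # vectors plus weak noise
        from scipy.optimize import linear_sum_assignment

        cps_true = cn.generate_cp_matrices(C=12, k_true=3, seed=6)
        iu = np.triu_indices(12, k=1)
        truth = np.vstack([cp.correlation_matrix[iu] for cp in cps_true])
        A = rng.dirichlet(np.full(3, 0.3), size=800)  # mostly-pure mixtures
        X = A @ truth + 0.05 * rng.normal(size=(800, truth.shape[1]))
        cps = decompose_cps(X, k=3, seed=0)
        C = np.corrcoef(np.vstack([truth, cps.patterns]))[:3, 3:]
        ri, ci = linear_sum_assignment(-np.abs(C))
        assert np.abs(C[ri, ci]).mean() > 0.9

    def test_single_component_matches_principal_direction(self, rng):
        # PCA oracle on a symmetric Gaussian fixture: with one component the
        # whitened ICA direction spans the first principal axis
        direction = rng.normal(size=20)
        direction /= np.linalg.norm(direction)
        X = np.outer(rng.normal(size=500), direction) * 3 + 0.1 * rng.normal(size=(500, 20))
        cps = decompose_cps(X, k=1, seed=0)
        u = np.linalg.svd(X - X.mean(0), full_matrices=False)[2][0]
        r = np.corrcoef(cps.patterns[0], u)[0, 1]
        assert abs(r) > 0.99

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(100, 20))
        a = decompose_cps(X, k=3, seed=5)
        b = decompose_cps(X, k=3, seed=5)
        np.testing.assert_array_equal(a.patterns, b.patterns)

    def test_sign_convention(self, rng):
        X = rng.normal(size=(100, 15))
        cps = decompose_cps(X, k=4, seed=2)
        for row in cps.patterns:
            assert row[np.argmax(np.abs(row))] > 0


class TestProjectToCps:
    def test_exact_linear_recovery(self, rng):
        # orthonormalized mean-zero patterns; fnc row = 2*CP1 - 1*CP3
        M = rng.normal(size=(40, 5))
        M -= M.mean(axis=0)  # columns orthogonal to the intercept
        Q, _ = np.linalg.qr(M)
        pats = Q.T  # 5 x 40 orthonormal rows
        cps = ConnectivityPatterns(k=5, patterns=pats, algorithm_seed=0)
        row = 2 * pats[0] - 1 * pats[2]
        w = project_to_cps(row, cps)
        np.testing.assert_allclose(w[0], [2, 0, -1, 0, 0], atol=1e-10)

    def test_orthogonal_row_gives_zero_weights(self, rng):
        M = rng.normal(size=(40, 6))
        M -= M.mean(axis=0)  # keep the intercept out of the pattern span
        Q, _ = np.linalg.qr(M)
        cps = ConnectivityPatterns(k=5, patterns=Q.T[:5], algorithm_seed=0)
        w = project_to_cps(Q.T[5], cps)
        np.testing.assert_allclose(w[0], 0, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        pats = rng.normal(size=(4, 30))
        cps = ConnectivityPatterns(k=4, patterns=pats, algorithm_seed=0)
        X = rng.normal(size=(12, 30))
        W = project_to_cps(X, cps)
        D = np.column_stack([np.ones(30), pats.T])
        expected = (np.linalg.inv(D.T @ D) @ D.T @ X.T)[1:].T
        np.testing.assert_allclose(W, expected, atol=1e-10)


class TestDiscretize:
    def test_constructed_fixed_point(self):
        # reference holding +-1..+-4 replicated equally maps onto itself
        base = np.array([-4, -3, -2, -1, 1, 2, 3, 4], dtype=float)
        ref = np.tile(base, 8)[:, None]
        out = discretize_quartiles(ref, ref)
        np.testing.assert_array_equal(out[:, 0], np.tile(base, 8).astype(int))

    def test_all_positive_column_quartile_counts(self, rng):
        ref = rng.uniform(0.1, 5.0, size=(400, 1))
        with pytest.warns(UserWarning, match="one-sided"):
            out = discretize_quartiles(ref, ref)
        assert set(np.unique(out)) <= {1, 2, 3, 4}
        counts = np.bincount(out[:, 0], minlength=5)[1:]
        assert np.all(np.abs(counts - 100) <= 1)

    def test_scale_equivariance(self, rng):
        w = rng.normal(size=(60, 3))
        ref = rng.normal(size=(500, 3))
        a = discretize_quartiles(w, ref)
        w2, ref2 = w.copy(), ref.copy()
        w2[:, 1] *= 10
        ref2[:, 1] *= 10
        np.testing.assert_array_equal(a, discretize_quartiles(w2, ref2))

    def test_zeros_map_to_plus_one(self, rng):
        ref = rng.normal(size=(200, 1))
        w = np.zeros((5, 1))
        np.testing.assert_array_equal(discretize_quartiles(w, ref), 1)

    def test_no_zero_bins_and_signs_match(self, rng):
        ref = rng.normal(size=(300, 4))
        w = rng.normal(size=(50, 4))
        out = discretize_quartiles(w, ref)
        assert not np.any(out == 0)
        assert np.all((out > 0) == (w >= 0))


class TestMetrics:
    def test_constant_trajectory(self):
        D = np.tile([1, -2, 3, 4, -1], (10, 1))
        m = metastate_metrics(D)
        assert (m.n_states, m.n_changes, m.span, m.total_distance) == (1, 0, 0, 0)

    def test_hand_enumerated_example(self):
        D = np.array([[1, 1, 1, 1, 1], [2, 1, 1, 1, 1], [1, 1, 1, 1, 1]])
        m = metastate_metrics(D)
        assert (m.n_states, m.n_changes, m.span, m.total_distance) == (2, 2, 1, 2)

    def test_alternating_closed_form(self):
        A = np.array([1, 1, 2, -1])
        B = np.array([3, 1, 1, -2])
        d = int(np.abs(A - B).sum())
        D = np.vstack([A, B] * 4)  # 7 transitions
        m = metastate_metrics(D)
        assert m.n_states == 2
        assert m.n_changes == 7
        assert m.total_distance == 7 * d
        assert m.span == d

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=200, deadline=None)
    def test_matches_bruteforce_oracle(self, seed):
        D = random_trajectory(np.random.default_rng(seed))
        m = metastate_metrics(D)
        assert (m.n_states, m.n_changes, m.span, m.total_distance) == metrics_bruteforce(D)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=100, deadline=None)
    def test_invariants_hold(self, seed):
        D = random_trajectory(np.random.default_rng(seed))
        W, k = D.shape
        m = metastate_metrics(D)
        assert 1 <= m.n_states <= min(W, 8**k)
        assert 0 <= m.n_changes <= W - 1
        assert m.n_states <= m.n_changes + 1
        assert m.span <= 8 * k
        if m.n_changes >= 1:
            assert m.total_distance >= m.span

    def test_column_permutation_invariance(self, rng):
        D = random_trajectory(rng, W=50, k=6)
        perm = rng.permutation(6)
        a = metastate_metrics(D)
        b = metastate_metrics(D[:, perm])
        assert a == b


class TestStateSpace:
    def test_five_patterns_eight_bins(self):
        assert possible_state_count(5, 8) == 32768

    @pytest.mark.parametrize("k,expected", [(1, 8), (4, 4096)])
    def test_powers(self, k, expected):
        assert possible_state_count(k, 8) == expected

    def test_occupancy_percentage(self):
        assert occupancy_fraction(72.1, 5, 8) == 0.22
        assert occupancy_fraction(0, 5, 8) == 0.0
        assert occupancy_fraction(32768, 5, 8) == 100.0


class TestSweep:
    def test_single_k_equals_direct_pipeline(self, small_cohort):
        spec = cn.WindowSpec()
        fncs = [
            cn.compute_windowed_fnc(
                cn.clean_timecourses(s.tc, s.motion, s.TR), spec, 0.0, s.subject_id
            )
            for s in small_cohort.subjects
        ]
        cps_by_k, table = sweep_dimensionality(fncs, k_list=(3,), seed=4)
        _, _, direct = cn.compute_group_metastates(fncs, k=3, seed=4)
        merged = table.drop(columns="k")
        np.testing.assert_array_equal(
            merged.to_numpy(), direct.to_numpy()
        )

    def test_deterministic(self, small_cohort):
        spec = cn.WindowSpec()
        fncs = [
            cn.compute_windowed_fnc(
                cn.clean_timecourses(s.tc, s.motion, s.TR), spec, 0.0, s.subject_id
            )
            for s in small_cohort.subjects
        ]
        _, a = sweep_dimensionality(fncs, k_list=(2, 3), seed=9)
        _, b = sweep_dimensionality(fncs, k_list=(2, 3), seed=9)
        assert a.equals(b)
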