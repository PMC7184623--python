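"""Sliding-window FNC: taper, weighted moments, graphical lasso, assembly.

The graphical-lasso path is checked against an independently written
block-coordinate-descent solver (Friedman-style, with its own cyclic lasso
inner loop) so the production path (scikit-learn) and the oracle share no
code.
"""

import numpy as np
import pytest

import chronnectome as cn
from chronnectome.dfnc import GlassoError, glasso_correlation, make_taper


# ---------------------------------------------------------------- oracles


def conv_oracle(width, sigma):
    """Naive O(n^2) direct-sum convolution of rectangle and Gaussian."""
    radius = int(np.ceil(4 * sigma))
    t = np.arange(-radius, radius + 1)
    kern = np.exp(-(t**2) / (2 * sigma**2))
    kern /= kern.sum()
    rect = np.ones(width)
    full = np.zeros(width + len(kern) - 1)
    for i in range(width):
        for j in range(len(kern)):
            full[i + j] += rect[i] * kern[j]
    taper = full[radius : radius + width]
    return taper * width / taper.sum()


def weighted_corr_loop(segment, taper):
    """Elementwise-loop implementation of the taper-weighted correlation."""
    w = taper / taper.sum()
    width, C = segment.shape
    mu = np.zeros(C)
    for t in range(width):
        mu += w[t] * segment[t]
    S = np.zeros((C, C))
    for t in range(width):
        d = segment[t] - mu
        for i in range(C):
            for j in range(C):
                S[i, j] += w[t] * d[i] * d[j]
    R = np.empty_like(S)
    for i in range(C):
        for j in range(C):
            R[i, j] = S[i, j] / np.sqrt(S[i, i] * S[j, j])
    return R


def _lasso_cd(G, b, lam, n_iter=2000, tol=1e-12):
    """Cyclic coordinate descent for 0.5 x'Gx - b'x + lam |x|_1."""
    p = len(b)
    x = np.zeros(p)
    for _ in range(n_iter):
        x_old = x.copy()
        for j in range(p):
            r = b[j] - G[j] @ x + G[j, j] * x[j]
            x[j] = np.sign(r) * max(abs(r) - lam, 0.0) / G[j, j]
        if np.abs(x - x_old).max() < tol:
            break
    return x


def glasso_oracle(S, lam, n_sweeps=500, tol=1e-12):
    """Block-coordinate-descent graphical lasso on covariance S.

    Off-diagonal-only L1 penalty (the convention of the production solver):
    the working covariance keeps diag(S) fixed and each column is updated by
    an explicit cyclic-coordinate-descent lasso on the remaining block.
    """
    p = S.shape[0]
    W = S.copy()
    for _ in range(n_sweeps):
        W_old = W.copy()
        for j in range(p):
            idx = np.array([i for i in range(p) if i != j])
            W11 = W[np.ix_(idx, idx)]
            s12 = S[idx, j]
            beta = _lasso_cd(W11, s12, lam)
            W[idx, j] = W11 @ beta
            W[j, idx] = W[idx, j]
        if np.abs(W - W_old).max() < tol:
            break
    return W


# ------------------------------------------------------------------ taper


class TestTaper:
    @pytest.mark.parametrize("width,sigma", [(30, 3.0), (20, 1.5), (44, 5.0)])
    def test_symmetric_unimodal(self, width, sigma):
        w = make_taper(width, sigma)
        assert w.shape == (width,)
        np.testing.assert_allclose(w, w[::-1], atol=1e-12)
        mid = width // 2
        # maximum attained at the center (possibly a flat central plateau)
        assert w[mid] == pytest.approx(w.max(), abs=1e-12)
        assert np.all(np.diff(w[:mid]) >= -1e-12)

    def test_tiny_sigma_approaches_rectangle(self):
        w = make_taper(30, 0.01)
        np.testing.assert_allclose(w, 1.0, atol=1e-3)

    def test_matches_naive_convolution_oracle(self):
        np.testing.assert_allclose(make_taper(30, 3.0), conv_oracle(30, 3.0), atol=1e-12)

    def test_normalized_to_width(self):
        assert make_taper(30, 3.0).sum() == pytest.approx(30.0)


class TestWindowStarts:
    def test_default_geometry(self):
        starts = cn.window_starts(200, cn.WindowSpec())
        assert len(starts) == 171
        assert starts[0] == 0 and starts[-1] == 170

    def test_single_window(self):
        assert cn.window_starts(30, cn.WindowSpec()).tolist() == [0]

    def test_too_short_series(self):
        with pytest.raises(ValueError, match="29"):
            cn.window_starts(29, cn.WindowSpec())

    @pytest.mark.parametrize("T,width,step", [(100, 30, 1), (100, 30, 5), (64, 16, 3)])
    def test_count_formula(self, T, width, step):
        spec = cn.WindowSpec(width=width, step=step)
        assert len(cn.window_starts(T, spec)) == (T - width) // step + 1


class TestWeightedCorrelation:
    def test_uniform_taper_equals_sample_correlation(self, rng):
        seg = rng.normal(size=(30, 4))
        R = cn.weighted_correlation(seg, np.ones(30))
        expected = np.corrcoef(seg, rowvar=False)
        np.testing.assert_allclose(R, expected, atol=1e-12)

    def test_taper_scale_invariance(self, rng):
        seg = rng.normal(size=(30, 4))
        taper = make_taper(30, 3.0)
        np.testing.assert_allclose(
            cn.weighted_correlation(seg, taper),
            cn.weighted_correlation(seg, 7 * taper),
            atol=1e-12,
        )

    def test_matches_loop_oracle(self, rng):
        seg = rng.normal(size=(30, 4))
        taper = make_taper(30, 3.0)
        np.testing.assert_allclose(
            cn.weighted_correlation(seg, taper), weighted_corr_loop(seg, taper), atol=1e-12
        )

    def test_zero_variance_component_rejected(self, rng):
        seg = rng.normal(size=(30, 3))
        seg[:, 1] = 4.2
        with pytest.raises(ValueError, match="zero-variance"):
            cn.weighted_correlation(seg, np.ones(30))


class TestGlasso:
    def test_unpenalized_limit_equals_weighted_correlation(self, rng):
        seg = rng.normal(size=(40, 5))
        taper = make_taper(40, 3.0)
        np.testing.assert_allclose(
            glasso_correlation(seg, taper, lam=0.0),
            cn.weighted_correlation(seg, taper),
            atol=1e-6,
        )

    def test_full_shrinkage_kills_off_diagonals(self, rng):
        seg = rng.normal(size=(30, 5))
        taper = make_taper(30, 3.0)
        R = glasso_correlation(seg, taper, lam=2.0)
        off = R[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 1e-3

    def test_matches_independent_coordinate_descent_oracle(self, rng):
        seg = rng.normal(size=(30, 6))
        taper = make_taper(30, 3.0)
        R = glasso_correlation(seg, taper, lam=0.1, tol=1e-8)
        S = cn.weighted_correlation(seg, taper)
        W = glasso_oracle(S, 0.1)
        d = np.sqrt(np.diag(W))
        expected = W / np.outer(d, d)
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(R, expected, atol=1e-4)

    def test_result_positive_definite_and_bounded(self, rng):
        seg = rng.normal(size=(30, 8))
        taper = make_taper(30, 3.0)
        R = glasso_correlation(seg, taper, lam=0.1)
        assert np.linalg.eigvalsh(R).min() > 0
        off = R[~np.eye(8, dtype=bool)]
        assert np.all(np.abs(off) < 1)


class TestSelectLambda:
    def test_singleton_grid_returned_without_cv(self, rng):
        tc = rng.normal(size=(120, 5))
        lam = cn.select_lambda(tc, cn.WindowSpec(), grid=[0.25])
        assert lam == 0.25

    def test_deterministic_given_seed(self, small_cohort):
        tc = small_cohort.subjects[0].tc
        spec = cn.WindowSpec()
        a = cn.select_lambda(tc, spec, seed=3)
        b = cn.select_lambda(tc, spec, seed=3)
        assert a == b

    def test_sparse_precision_data_prefers_positive_penalty(self, rng):
        # data from a sparse-precision model; held-out likelihood at the
        # selected lambda must be a grid maximum by construction
        prec = np.eye(6)
        prec[0, 1] = prec[1, 0] = 0.4
        cov = np.linalg.inv(prec)
        L = np.linalg.cholesky(cov)
        tc = rng.standard_normal((150, 6)) @ L.T
        lam = cn.select_lambda(tc, cn.WindowSpec(), seed=0)
        assert lam > 0

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            cn.select_lambda(rng.normal(size=(60, 3)), cn.WindowSpec(), grid=[])


class TestWindowedFnc:
    def test_default_shape_contract(self, rng):
        tc = rng.normal(size=(200, 8))
        fnc = cn.compute_windowed_fnc(tc, cn.WindowSpec(), lam=0.05)
        assert fnc.fnc.shape == (171, 28)
        assert fnc.pair_index[0] == (0, 1) and fnc.pair_index[-1] == (6, 7)
        assert len(set(fnc.pair_index)) == 28

    def test_stationary_data_recovers_generating_pattern(self):
        # windows share data, so the window-mean has full-sample variance:
        # T is chosen long enough that sampling error sits well under 0.1
        cps = cn.generate_cp_matrices(C=6, k_true=1, seed=5)
        seq = cn.generate_state_sequence(T=2000, k_true=1, switch_rate=0.0, seed=5)
        tc = cn.generate_timecourses(cps, seq, noise_sd=0.0, seed=5)
        fnc = cn.compute_windowed_fnc(tc, cn.WindowSpec(), lam=0.03)
        iu = np.triu_indices(6, k=1)
        truth = cps[0].correlation_matrix[iu]
        assert np.abs(fnc.fnc.mean(axis=0) - truth).max() < 0.1

    def test_two_components_give_single_pair(self, rng):
        tc = rng.normal(size=(100, 2))
        fnc = cn.compute_windowed_fnc(tc, cn.WindowSpec(), lam=0.0)
        assert fnc.fnc.shape == (71, 1)

    def test_entries_strictly_inside_unit_interval(self, small_cohort):
        sub = small_cohort.subjects[0]
        fnc = cn.compute_windowed_fnc(sub.tc, cn.WindowSpec(), lam=0.05)
        assert np.all(np.abs(fnc.fnc) < 1)

    def test_time_reversal_reverses_window_order(self, rng):
        tc = rng.normal(size=(80, 4))
        spec = cn.WindowSpec()
        fwd = cn.compute_windowed_fnc(tc, spec, lam=0.0)
        rev = cn.compute_windowed_fnc(tc[::-1], spec, lam=0.0)
        np.testing.assert_allclose(fwd.fnc, rev.fnc[::-1], atol=1e-10)

    def test_lambda_zero_on_singular_window_raises_with_index(self, rng):
        tc = np.zeros((40, 3))
        tc[:, 0] = rng.normal(size=40)
        tc[:, 1] = rng.normal(size=40)
        tc[:, 2] = 1.0  # constant component
        with pytest.raises((GlassoError, ValueError)):
            cn.compute_windowed_fnc(tc, cn.WindowSpec(), lam=0.0)
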