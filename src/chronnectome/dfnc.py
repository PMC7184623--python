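"""Tapered sliding-window regularized functional network connectivity.

Each subject's cleaned T x C component time-course matrix is cut into
overlapping windows (default width 30 TR, step 1 TR) weighted by a taper
built by convolving a rectangle with a Gaussian (sigma = 3 TR). Within each
window a taper-weighted covariance is estimated and regularized with the
graphical lasso (L1 penalty on the precision matrix, iteration budget 100),
since a 30-sample window cannot support an unregularized 37 x 37 estimate.
The per-window estimates are returned as correlation matrices and vectorized
over the C(C-1)/2 component pairs into the windowed FNC matrix.

The penalty lambda is selected once per subject by cross-validation over
windows (see :func:`select_lambda`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance._graph_lasso import _graphical_lasso

__all__ = [
    "WindowSpec",
    "WindowedFNC",
    "DEFAULT_LAMBDA_GRID",
    "DEFAULT_GLASSO_TOL",
    "make_taper",
    "window_starts",
    "weighted_correlation",
    "glasso_correlation",
    "select_lambda",
    "compute_windowed_fnc",
]

#: default log-spaced penalty grid, 10 values in [0.03, 1]; the floor is set
#: by solver feasibility on rank-deficient 30-frame windows (below ~0.03 the
#: coordinate-descent graphical lasso goes non-SPD on a subset of windows)
DEFAULT_LAMBDA_GRID = tuple(np.logspace(np.log10(0.03), 0.0, 10))


class GlassoError(RuntimeError):
    """Graphical-lasso failure, annotated with window index and lambda."""

    def __init__(self, message: str, window: int | None = None, lam: float | None = None):
        super().__init__(message)
        self.window = window
        self.lam = lam


def make_taper(width: int = 30, gauss_sigma: float = 3.0) -> np.ndarray:
    """Taper weights: rectangle of ``width`` convolved with a Gaussian.

    The Gaussian kernel has unit area and support +-4 sigma; the full
    convolution is truncated to its central ``width`` samples and renormalized
    to sum to ``width``. The result is symmetric and unimodal.
    """
    if width < 2:
        raise ValueError("width must be >= 2")
    if gauss_sigma <= 0:
        raise ValueError("gauss_sigma must be > 0")
    radius = int(np.ceil(4 * gauss_sigma))
    t = np.arange(-radius, radius + 1)
    kernel = np.exp(-(t**2) / (2 * gauss_sigma**2))
    kernel /= kernel.sum()
    full = np.convolve(np.ones(width), kernel)  # length width + 2*radius
    taper = full[radius : radius + width]
    return taper * (width / taper.sum())


@dataclass
class WindowSpec:
    """Sliding-window geometry and taper."""

    width: int = 30
    step: int = 1
    gauss_sigma: float = 3.0
    taper: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.width < 2:
            raise ValueError("width must be >= 2")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.taper is None:
            self.taper = make_taper(self.width, self.gauss_sigma)
        self.taper = np.asarray(self.taper, dtype=float)
        if self.taper.shape != (self.width,):
            raise ValueError("taper length must equal width")
        if np.any(self.taper <= 0):
            raise ValueError("taper weights must be positive")


def window_starts(T: int, spec: WindowSpec) -> np.ndarray:
    """0-based start indices of the full windows [s, s + width) within T."""
    if T < spec.width:
        raise ValueError(f"T = {T} is shorter than the window width {spec.width}")
    return np.arange(0, T - spec.width + 1, spec.step)


def _weighted_cov(segment: np.ndarray, taper: np.ndarray) -> np.ndarray:
    w = taper / taper.sum()
    mu = w @ segment
    xc = segment - mu
    return (xc * w[:, None]).T @ xc


def weighted_correlation(segment: np.ndarray, taper: np.ndarray) -> np.ndarray:
    """Taper-weighted correlation matrix of one window segment.

    Invariant to any positive rescaling of the taper; with a uniform taper it
    equals the ordinary (population-normalized) sample correlation.
    """
    segment = np.asarray(segment, dtype=float)
    taper = np.asarray(taper, dtype=float)
    if segment.ndim != 2:
        raise ValueError("segment must be 2-D (width x C)")
    if taper.shape != (segment.shape[0],):
        raise ValueError("taper length must match segment rows")
    if taper.sum() <= 0:
        raise ValueError("taper must have positive sum")
    S = _weighted_cov(segment, taper)
    d = np.sqrt(np.diag(S))
    if np.any(d <= 1e-10 * max(float(d.max()), 1e-300)):
        raise ValueError("zero-variance component within window")
    R = S / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


#: default duality-gap tolerance for the graphical-lasso solver; loose enough
#: to converge in a handful of sweeps per window (estimates change by ~1e-3,
#: far below the sampling noise of a 30-frame window)
DEFAULT_GLASSO_TOL = 1e-3


def _glasso_fit(
    S: np.ndarray,
    lam: float,
    max_iter: int = 100,
    cov_init: np.ndarray | None = None,
    tol: float = DEFAULT_GLASSO_TOL,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the graphical lasso to a correlation matrix; returns (cov, prec).

    Warm-startable via ``cov_init``; falls back to a cold start if the
    warm-started solve goes non-SPD.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cov, prec, *_ = _graphical_lasso(
                S, alpha=lam, cov_init=cov_init, max_iter=max_iter, tol=tol
            )
        except FloatingPointError:
            if cov_init is None:
                raise
            cov, prec, *_ = _graphical_lasso(S, alpha=lam, cov_init=None, max_iter=max_iter, tol=tol)
    return cov, prec


def glasso_correlation(
    segment: np.ndarray,
    taper: np.ndarray,
    lam: float,
    max_iter: int = 100,
    cov_init: np.ndarray | None = None,
    tol: float = DEFAULT_GLASSO_TOL,
) -> np.ndarray:
    """L1-regularized windowed correlation matrix.

    The taper-weighted covariance is normalized to a correlation matrix and
    fed to the graphical lasso with penalty ``lam``; the fitted covariance is
    renormalized to unit diagonal. ``lam = 0`` is the exact unpenalized limit
    and returns the weighted sample correlation directly.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam == 0:
        return weighted_correlation(segment, taper)
    segment = np.asarray(segment, dtype=float)
    taper = np.asarray(taper, dtype=float)
    S = _weighted_cov(segment, taper)
    d = np.sqrt(np.diag(S))
    # at lam > 0 a zero-variance component is tolerated: its variance is
    # floored so the solver runs; its off-diagonals shrink to zero
    thr = 1e-10 * max(float(d.max()), 1e-300)
    d = np.where(d > thr, d, np.sqrt(lam))
    R = S / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    try:
        cov, _ = _glasso_fit(R, lam, max_iter=max_iter, cov_init=cov_init, tol=tol)
        if not _sane_corr_fit(cov):
            if cov_init is None:
                raise FloatingPointError("diverged covariance estimate")
            cov, _ = _glasso_fit(R, lam, max_iter=max_iter, cov_init=None, tol=tol)
            if not _sane_corr_fit(cov):
                raise FloatingPointError("diverged covariance estimate")
    except FloatingPointError as e:
        raise GlassoError(f"graphical lasso failed at lambda={lam}: {e}", lam=lam) from e
    dd = np.sqrt(np.diag(cov))
    out = cov / np.outer(dd, dd)
    np.fill_diagonal(out, 1.0)
    return out


def _sane_corr_fit(cov: np.ndarray) -> bool:
    """A fitted covariance usable as a correlation source: finite, positive
    diagonal, off-diagonal correlations strictly below 1 (the solver can
    silently diverge when warm-started across windows)."""
    if not np.all(np.isfinite(cov)):
        return False
    d = np.diag(cov)
    if np.any(d <= 0):
        return False
    dd = np.sqrt(d)
    off = cov / np.outer(dd, dd)
    np.fill_diagonal(off, 0.0)
    return bool(np.abs(off).max() < 1.0)


def _gaussian_loglik(prec: np.ndarray, S_test: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(prec)
    if sign <= 0:
        return -np.inf
    return float(logdet - np.trace(S_test @ prec))


def select_lambda(
    tc: np.ndarray,
    spec: WindowSpec,
    grid: tuple[float, ...] | list[float] | None = None,
    n_folds: int = 5,
    seed: int = 0,
    n_probe_windows: int = 3,
    max_iter: int = 100,
    tol: float = DEFAULT_GLASSO_TOL,
) -> float:
    """Select the graphical-lasso penalty by cross-validation over windows.

    Windows are shuffled into ``n_folds`` folds; for every penalty the model
    is fitted to the mean training-window correlation and scored by the
    Gaussian log-likelihood of the held-out windows (the standard predictive-
    likelihood criterion for sparse inverse-covariance selection). Before
    scoring, the grid is restricted to penalties at which single windows can
    actually be fitted (probed on a small window subsample): a penalty that
    cannot solve the rank-deficient per-window problem is useless downstream
    no matter how well it predicts. Deterministic given ``seed``.
    """
    if grid is None:
        grid = DEFAULT_LAMBDA_GRID
    grid = sorted(float(g) for g in grid)
    if not grid:
        raise ValueError("lambda grid must be non-empty")
    if any(g <= 0 for g in grid):
        raise ValueError("grid lambdas must be > 0")
    if len(grid) == 1:
        return grid[0]
    tc = np.asarray(tc, dtype=float)
    starts = window_starts(tc.shape[0], spec)
    corrs = []
    for s in starts:
        S = _weighted_cov(tc[s : s + spec.width], spec.taper)
        d = np.sqrt(np.diag(S))
        d = np.where(d > 0, d, 1.0)
        R = S / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
        corrs.append(R)
    corrs = np.asarray(corrs)
    rng = np.random.default_rng(seed)
    # feasibility probe: smallest grid value whose single-window fits succeed
    probe = rng.choice(len(corrs), size=min(n_probe_windows, len(corrs)), replace=False)
    feasible = len(grid) - 1
    for gi, g in enumerate(grid):
        try:
            for wi in probe:
                _glasso_fit(corrs[wi], g, max_iter=max_iter, tol=tol)
            feasible = gi
            break
        except FloatingPointError:
            continue
    grid_eff = grid[feasible:]
    if len(grid_eff) == 1:
        return grid_eff[0]
    order = rng.permutation(len(corrs))
    folds = np.array_split(order, min(n_folds, len(corrs)))
    scores = {g: [] for g in grid_eff}
    for fold in folds:
        if fold.size == 0:
            continue
        train = np.setdiff1d(order, fold)
        S_train = corrs[train].mean(axis=0)
        S_test = corrs[fold].mean(axis=0)
        cov_prev = None
        for g in grid_eff[::-1]:  # descending, homotopy warm start
            try:
                cov_prev, prec = _glasso_fit(
                    S_train, g, max_iter=max_iter, cov_init=cov_prev, tol=tol
                )
                scores[g].append(_gaussian_loglik(prec, S_test))
            except FloatingPointError:
                cov_prev = None
                scores[g].append(-np.inf)
    mean_scores = {g: (np.mean(v) if v else -np.inf) for g, v in scores.items()}
    best = max(grid_eff, key=lambda g: mean_scores[g])
    if not np.isfinite(mean_scores[best]):
        raise GlassoError("all cross-validation fits failed", lam=None)
    return best


@dataclass
class WindowedFNC:
    """Per-subject windowed FNC: W windows x P = C(C-1)/2 component pairs."""

    subject_id: str
    fnc: np.ndarray  # W x P
    pair_index: list[tuple[int, int]]
    lam: float
    spec: WindowSpec = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def n_windows(self) -> int:
        return self.fnc.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.fnc.shape[1]


def compute_windowed_fnc(
    tc: np.ndarray,
    spec: WindowSpec,
    lam: float,
    subject_id: str = "",
    max_iter: int = 100,
    fisher_z: bool = False,
    tol: float = DEFAULT_GLASSO_TOL,
) -> WindowedFNC:
    """Assemble the W x P windowed FNC matrix for one subject.

    Each window's regularized correlation matrix is vectorized over its upper
    triangle in row-major pair order (i < j). Consecutive windows share 29 of
    30 frames, so the graphical lasso is warm-started from the previous
    window's solution.
    """
    tc = np.asarray(tc, dtype=float)
    starts = window_starts(tc.shape[0], spec)
    C = tc.shape[1]
    iu = np.triu_indices(C, k=1)
    pair_index = list(zip(iu[0].tolist(), iu[1].tolist()))
    fnc = np.empty((len(starts), len(pair_index)))
    cov_prev = None
    for w, s in enumerate(starts):
        segment = tc[s : s + spec.width]
        try:
            if lam == 0:
                R = weighted_correlation(segment, spec.taper)
            else:
                S = _weighted_cov(segment, spec.taper)
                d = np.sqrt(np.diag(S))
                d = np.where(d > 0, d, np.sqrt(lam))
                Rw = S / np.outer(d, d)
                np.fill_diagonal(Rw, 1.0)
                cov_prev, _ = _glasso_fit(Rw, lam, max_iter=max_iter, cov_init=cov_prev, tol=tol)
                if not _sane_corr_fit(cov_prev):  # warm-start poisoning: restart cold
                    cov_prev, _ = _glasso_fit(Rw, lam, max_iter=max_iter, cov_init=None, tol=tol)
                    if not _sane_corr_fit(cov_prev):
                        raise FloatingPointError("diverged covariance estimate")
                dd = np.sqrt(np.diag(cov_prev))
                R = cov_prev / np.outer(dd, dd)
        except (FloatingPointError, ValueError) as e:
            raise GlassoError(
                f"window {w} (start {s}) failed at lambda={lam}: {e}", window=w, lam=lam
            ) from e
        fnc[w] = R[iu]
    if fisher_z:
        fnc = np.arctanh(np.clip(fnc, -1 + 1e-12, 1 - 1e-12))
    return WindowedFNC(subject_id=subject_id, fnc=fnc, pair_index=pair_index, lam=lam, spec=spec)
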