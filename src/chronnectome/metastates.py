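"""Connectivity-pattern decomposition and meta-state fluidity metrics.

The stacked windowed-FNC matrix (all subjects' windows by all component
pairs) is decomposed with spatial ICA into ``k`` connectivity patterns (CPs,
default 5), treating the pair axis as space. Each subject's window-wise FNC
is regressed onto the CP basis to give continuous CP weight time-courses,
which are discretized into 8 signed-quartile bins (+-1..+-4). The discrete
k-vector at each window is the subject's meta-state; four scalar indexes
summarize how fluidly the subject moves through the 8^k meta-state space:

* number of distinct meta-states occupied,
* number of switches between successive meta-states,
* span (largest L1 distance between two occupied meta-states),
* total distance (summed L1 distance between successive meta-states).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .dfnc import WindowedFNC

__all__ = [
    "ConnectivityPatterns",
    "MetaStateTrajectory",
    "MetaStateMetrics",
    "decompose_cps",
    "project_to_cps",
    "discretize_quartiles",
    "metastate_metrics",
    "possible_state_count",
    "occupancy_fraction",
    "compute_group_metastates",
    "sweep_dimensionality",
]

METRIC_NAMES = ("n_states", "n_changes", "span", "total_distance")


@dataclass
class ConnectivityPatterns:
    """Group-level CP basis: k loading rows over the P component pairs."""

    k: int
    patterns: np.ndarray  # k x P
    algorithm_seed: int

    def validate(self) -> None:
        if self.patterns.shape[0] != self.k:
            raise ValueError("patterns row count must equal k")
        tol = 1e-8 * np.linalg.norm(self.patterns)
        if np.linalg.matrix_rank(self.patterns, tol=tol) < self.k:
            raise ValueError("CP rows must be linearly independent")


@dataclass
class MetaStateTrajectory:
    """Per-subject continuous CP weights and their discretized meta-states."""

    subject_id: str
    weights: np.ndarray  # W x k, continuous
    discrete: np.ndarray  # W x k, integers in {-4..-1, +1..+4}


@dataclass(frozen=True)
class MetaStateMetrics:
    n_states: int
    n_changes: int
    span: int
    total_distance: int

    def as_dict(self) -> dict[str, int]:
        return {
            "n_states": self.n_states,
            "n_changes": self.n_changes,
            "span": self.span,
            "total_distance": self.total_distance,
        }


def decompose_cps(all_fnc: np.ndarray, k: int = 5, seed: int = 0) -> ConnectivityPatterns:
    """Spatial ICA of the stacked windowed FNC into k connectivity patterns.

    The P-dimensional pair axis plays the role of space: the N x P input is
    modeled as mixing x sources with k independent spatial sources (the CP
    loading rows). Whitening retains k principal components. Components are
    sign-fixed so each pattern's largest-magnitude loading is positive and
    ordered by explained variance (descending). Non-convergence is retried
    with two alternate internal seeds before raising.
    """
    all_fnc = np.asarray(all_fnc, dtype=float)
    if all_fnc.ndim != 2:
        raise ValueError("all_fnc must be 2-D (windows x pairs)")
    N, P = all_fnc.shape
    if N < k or P < k:
        raise ValueError(f"need at least k={k} rows and columns, got {all_fnc.shape}")
    last_err: Exception | str | None = None
    # deflation first (symmetric updates can oscillate on this data); a
    # symmetric attempt as the final fallback
    for rs, algorithm in ((seed, "deflation"), (seed + 1000, "deflation"),
                          (seed + 2000, "parallel")):
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                ica = FastICA(
                    n_components=k,
                    random_state=rs,
                    whiten="unit-variance",
                    algorithm=algorithm,
                    max_iter=2000,
                    tol=1e-4,
                )
                sources = ica.fit_transform(all_fnc.T)  # P x k
            except ConvergenceWarning as e:  # retry with a different seed
                last_err = e
                continue
        # deflation can stall on a duplicated source; that run is unusable
        if np.linalg.matrix_rank(sources.T, tol=1e-8 * np.linalg.norm(sources)) < k:
            last_err = "duplicate/degenerate components"
            continue
        break
    else:
        raise RuntimeError(f"FastICA did not converge after 3 seeds: {last_err}")
    patterns = sources.T  # k x P
    mixing = ica.mixing_  # N x k
    # explained-variance ordering: sources have unit variance over P, so the
    # variance contributed by component j is ||mixing[:, j]||^2
    contrib = (mixing**2).sum(axis=0)
    order = np.argsort(contrib)[::-1]
    patterns = patterns[order]
    # sign convention: largest-|loading| entry positive
    for j in range(k):
        peak = np.argmax(np.abs(patterns[j]))
        if patterns[j, peak] < 0:
            patterns[j] = -patterns[j]
    cps = ConnectivityPatterns(k=k, patterns=patterns, algorithm_seed=seed)
    cps.validate()
    return cps


def project_to_cps(fnc: WindowedFNC | np.ndarray, cps: ConnectivityPatterns) -> np.ndarray:
    """Continuous CP weights: regress each window's FNC row on the CP basis.

    Ordinary least squares with an intercept; returns the W x k coefficient
    matrix (intercept dropped). A rank-deficient basis falls back to the
    pseudoinverse with a warning.
    """
    X = fnc.fnc if isinstance(fnc, WindowedFNC) else np.asarray(fnc, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    P = X.shape[1]
    if cps.patterns.shape[1] != P:
        raise ValueError("pair dimension mismatch between FNC and CPs")
    design = np.column_stack([np.ones(P), cps.patterns.T])  # P x (k+1)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn("rank-deficient CP design; using pseudoinverse")
        coef = np.linalg.pinv(design) @ X.T
    else:
        coef, *_ = np.linalg.lstsq(design, X.T, rcond=None)
    return coef[1:].T  # W x k


def _signed_quartile_edges(ref: np.ndarray) -> tuple[np.ndarray | None, np.ndarray | None]:
    pos = ref[ref > 0]
    neg = -ref[ref < 0]
    pos_edges = np.percentile(pos, [25, 50, 75]) if pos.size else None
    neg_edges = np.percentile(neg, [25, 50, 75]) if neg.size else None
    return pos_edges, neg_edges


def discretize_quartiles(weights: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Map continuous CP weights to 8 signed-quartile bins per CP.

    For each CP the quartile boundaries are computed separately over the
    positive reference values and over the magnitudes of the negative
    reference values (the reference is normally the pooled weights of all
    subjects, so bins are comparable across subjects). Positive weights map
    to +1..+4 by ascending quartile, negative weights to -1..-4 by ascending
    magnitude quartile. Exact zeros map to +1; values on a boundary fall in
    the lower bin.
    """
    W = np.asarray(weights, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if W.ndim == 1:
        W = W[:, None]
    if ref.ndim == 1:
        ref = ref[:, None]
    if W.shape[1] != ref.shape[1]:
        raise ValueError("weights and reference must have the same CP count")
    out = np.empty(W.shape, dtype=int)
    for j in range(W.shape[1]):
        pos_edges, neg_edges = _signed_quartile_edges(ref[:, j])
        if pos_edges is None or neg_edges is None:
            warnings.warn(f"CP {j}: one-sided reference distribution; single-sided binning")
        col = W[:, j]
        binned = np.ones(col.size, dtype=int)  # zeros -> +1
        pos = col > 0
        if pos.any():
            if pos_edges is not None:
                binned[pos] = 1 + np.searchsorted(pos_edges, col[pos], side="left")
            else:
                binned[pos] = 1
        neg = col < 0
        if neg.any():
            if neg_edges is not None:
                binned[neg] = -(1 + np.searchsorted(neg_edges, -col[neg], side="left"))
            else:
                binned[neg] = -1
        out[:, j] = binned
    return out


def metastate_metrics(discrete: np.ndarray) -> MetaStateMetrics:
    """The four meta-state fluidity indexes of one discrete trajectory.

    ``n_states`` counts distinct rows; ``n_changes`` counts time steps whose
    row differs from the previous one; ``span`` is the largest L1 distance
    between any two occupied meta-states; ``total_distance`` sums the L1
    distances between successive meta-states.
    """
    D = np.asarray(discrete)
    if D.ndim == 1:
        D = D[:, None]
    if D.shape[0] < 1:
        raise ValueError("trajectory must have at least one window")
    uniq = np.unique(D, axis=0)
    n_states = uniq.shape[0]
    if D.shape[0] > 1:
        step = np.abs(np.diff(D, axis=0)).sum(axis=1)
        n_changes = int(np.count_nonzero(step))
        total_distance = int(step.sum())
    else:
        n_changes = 0
        total_distance = 0
    if n_states > 1:
        diffs = np.abs(uniq[:, None, :] - uniq[None, :, :]).sum(axis=2)
        span = int(diffs.max())
    else:
        span = 0
    return MetaStateMetrics(
        n_states=int(n_states), n_changes=n_changes, span=span, total_distance=total_distance
    )


def possible_state_count(k: int, bins: int = 8) -> int:
    """Size of the discretized meta-state space, ``bins ** k``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return bins**k


def occupancy_fraction(mean_occupied: float, k: int, bins: int = 8) -> float:
    """Mean occupied meta-states as a percentage of the ``bins**k`` space."""
    if mean_occupied < 0:
        raise ValueError("mean_occupied must be >= 0")
    return round(100.0 * mean_occupied / possible_state_count(k, bins), 2)


def compute_group_metastates(
    fncs: list[WindowedFNC],
    k: int = 5,
    seed: int = 0,
    binning: str = "group",
) -> tuple[ConnectivityPatterns, list[MetaStateTrajectory], pd.DataFrame]:
    """Group CP decomposition, per-subject trajectories, and metrics table.

    ``binning="group"`` pools every subject's continuous weights as the
    quartile reference (bins comparable across subjects); ``"subject"`` bins
    each subject against its own weights.
    """
    if binning not in ("group", "subject"):
        raise ValueError("binning must be 'group' or 'subject'")
    stacked = np.vstack([f.fnc for f in fncs])
    cps = decompose_cps(stacked, k=k, seed=seed)
    weights = [project_to_cps(f, cps) for f in fncs]
    pooled = np.vstack(weights)
    trajectories: list[MetaStateTrajectory] = []
    rows = []
    for f, w in zip(fncs, weights):
        ref = pooled if binning == "group" else w
        disc = discretize_quartiles(w, ref)
        trajectories.append(MetaStateTrajectory(subject_id=f.subject_id, weights=w, discrete=disc))
        rows.append({"subject_id": f.subject_id, **metastate_metrics(disc).as_dict()})
    return cps, trajectories, pd.DataFrame(rows)


def sweep_dimensionality(
    fncs: list[WindowedFNC],
    k_list: list[int] | tuple[int, ...] = (4, 5, 6, 7, 8),
    seed: int = 0,
    binning: str = "group",
) -> tuple[dict[int, ConnectivityPatterns], pd.DataFrame]:
    """Re-run the meta-state pipeline for each model order k.

    Returns the per-k CP bases and a tidy (subject, k, metrics) table.
    Failures at one k are recorded and do not abort the remaining k.
    """
    cps_by_k: dict[int, ConnectivityPatterns] = {}
    frames = []
    errors: dict[int, str] = {}
    for k in k_list:
        try:
            cps, _, metrics = compute_group_metastates(fncs, k=k, seed=seed, binning=binning)
            metrics.insert(1, "k", k)
            cps_by_k[k] = cps
            frames.append(metrics)
        except Exception as e:  # noqa: BLE001 - isolate per-k failures
            errors[k] = str(e)
    if not frames:
        raise RuntimeError(f"every model order failed: {errors}")
    if errors:
        warnings.warn(f"model orders failed and were skipped: {errors}")
    return cps_by_k, pd.concat(frames, ignore_index=True)
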