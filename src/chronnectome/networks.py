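"""Subject-level network extraction against reference spatial maps.

Given a subject's voxels-by-time data matrix and a set of reference spatial
maps (intrinsic connectivity networks), this module produces subject-specific
spatial maps and time-courses two ways:

* :func:`dual_regression` — the standard two-stage least-squares baseline;
* :func:`constrained_ica` — one-unit negentropy ICA with a spatial-closeness
  penalty toward each reference map, initialized from dual regression, so the
  recovered components keep their reference identity while the ICA contrast
  denoises the maps.

This stage is optional in the main pipeline: the meta-state analysis is
usually driven directly by component time-courses (synthetic or precomputed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReferenceMaps",
    "SubjectDecomposition",
    "dual_regression",
    "constrained_ica",
    "mix_voxels",
    "load_nifti_maps",
    "save_nifti_maps",
]


@dataclass
class ReferenceMaps:
    """Reference spatial maps: V voxels by C components."""

    maps: np.ndarray  # V x C
    component_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2:
            raise ValueError("maps must be V x C")
        if self.maps.shape[1] < 1:
            raise ValueError("need at least one component")
        if np.any(np.all(self.maps == 0, axis=0)):
            raise ValueError("reference maps must not contain an all-zero column")
        if not self.component_ids:
            self.component_ids = [f"comp_{i:02d}" for i in range(self.maps.shape[1])]


@dataclass
class SubjectDecomposition:
    """Subject-specific maps (z-scored over voxels) and time-courses."""

    maps: np.ndarray  # V x C
    tc: np.ndarray  # T x C
    spatial_corr: np.ndarray  # length C
    method: str
    converged: np.ndarray | None = None  # per-component flags (constrained ICA)


def _zscore_cols(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def _corr_cols(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise correlation matrix between A (V x a) and B (V x b)."""
    Az = _zscore_cols(A)
    Bz = _zscore_cols(B)
    return Az.T @ Bz / A.shape[0]


def mix_voxels(refs: ReferenceMaps, tc: np.ndarray, noise_sd: float, seed: int) -> np.ndarray:
    """Forward model test fixture: data = maps @ tc.T + Gaussian noise."""
    tc = np.asarray(tc, dtype=float)
    if tc.ndim != 2 or tc.shape[1] != refs.maps.shape[1]:
        raise ValueError("tc must be T x C with C matching the reference maps")
    rng = np.random.default_rng(seed)
    data = refs.maps @ tc.T
    if noise_sd > 0:
        data = data + noise_sd * rng.standard_normal(data.shape)
    return data


def dual_regression(data: np.ndarray, refs: ReferenceMaps) -> SubjectDecomposition:
    """Two-stage least squares against the reference maps.

    Stage 1 regresses each volume on the reference maps (plus intercept) to
    obtain time-courses; stage 2 regresses each voxel's series on those
    time-courses to obtain subject maps. Maps and time-courses are z-scored
    and sign-fixed so each map correlates non-negatively with its reference.
    """
    data = np.asarray(data, dtype=float)
    V, T = data.shape
    if refs.maps.shape[0] != V:
        raise ValueError("voxel count mismatch between data and references")
    C = refs.maps.shape[1]
    if T < C:
        raise ValueError("need T >= C")
    D1 = np.column_stack([np.ones(V), refs.maps])
    if np.linalg.matrix_rank(D1) < D1.shape[1]:
        warnings.warn("rank-deficient reference maps; using pseudoinverse")
        tc = (np.linalg.pinv(D1) @ data)[1:].T  # T x C
    else:
        tc = np.linalg.lstsq(D1, data, rcond=None)[0][1:].T
    D2 = np.column_stack([np.ones(T), tc])
    maps = np.linalg.lstsq(D2, data.T, rcond=None)[0][1:].T  # V x C
    maps = _zscore_cols(maps)
    tc = _zscore_cols(tc)
    spatial_corr = np.array([_corr_cols(maps[:, [c]], refs.maps[:, [c]])[0, 0] for c in range(C)])
    flip = spatial_corr < 0
    maps[:, flip] *= -1
    tc[:, flip] *= -1
    spatial_corr = np.abs(spatial_corr)
    return SubjectDecomposition(maps=maps, tc=tc, spatial_corr=spatial_corr, method="dualreg")


def constrained_ica(
    data: np.ndarray,
    refs: ReferenceMaps,
    max_iter: int = 512,
    tol: float = 1e-6,
    constraint_weight: float = 1.0,
    mask: np.ndarray | None = None,
) -> SubjectDecomposition:
    """Spatially constrained one-unit ICA initialized from dual regression.

    The data are whitened over voxels (PCA to C spatial components). For each
    reference, a one-unit fixed-point iteration maximizes the log-cosh
    negentropy contrast of the spatial source plus a closeness term
    ``rho * corr(source, reference)``; the gradient of the closeness term is a
    constant vector in whitened space, so it acts as an anchor toward the
    reference. ``rho`` adapts upward if a component drifts closer to another
    reference than to its own. With ``max_iter=0`` the dual-regression
    initializer is returned unchanged.
    """
    data = np.asarray(data, dtype=float)
    init = dual_regression(data, refs)
    if max_iter == 0:
        init.method = "constrained_ica"
        init.converged = np.zeros(refs.maps.shape[1], dtype=bool)
        return init
    V, T = data.shape
    C = refs.maps.shape[1]
    if mask is None:
        mask = data.std(axis=1) > 0
    mask = np.asarray(mask, dtype=bool)
    Xm = data[mask]
    Vm = Xm.shape[0]
    # spatial whitening: PCA over volumes, keep C components of unit spatial
    # variance (columns of Y)
    Xc = Xm - Xm.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    n_keep = min(C, (s > 1e-12 * s[0]).sum())
    Y = U[:, :n_keep] * np.sqrt(Vm)
    refs_z = _zscore_cols(refs.maps[mask])
    P = Y.T @ refs_z / Vm  # n_keep x C: whitened-space reference directions
    W = np.zeros((n_keep, C))
    init_maps = _zscore_cols(init.maps[mask])
    converged = np.zeros(C, dtype=bool)
    for c in range(C):
        w = Y.T @ init_maps[:, c] / Vm
        nrm = np.linalg.norm(w)
        w = w / nrm if nrm > 0 else P[:, c] / max(np.linalg.norm(P[:, c]), 1e-12)
        rho = constraint_weight
        for _ in range(max_iter):
            s_src = Y @ w
            g = np.tanh(s_src)
            w_new = Y.T @ g / Vm - (1 - g**2).mean() * w + rho * P[:, c]
            w_new /= max(np.linalg.norm(w_new), 1e-12)
            if w_new @ P[:, c] < 0:
                w_new = -w_new
            delta = 1 - abs(w_new @ w)
            w = w_new
            if delta < tol:
                converged[c] = True
                break
        W[:, c] = w
    # identity guard: if a source is closer to a foreign reference, re-anchor
    # it with a stronger constraint
    S = Y @ W  # Vm x C sources
    cc = np.abs(_corr_cols(S, refs_z))
    for c in range(C):
        if cc[c, c] < cc[c].max() - 1e-12:
            w = P[:, c] / max(np.linalg.norm(P[:, c]), 1e-12)
            for _ in range(max_iter):
                s_src = Y @ w
                g = np.tanh(s_src)
                w_new = Y.T @ g / Vm - (1 - g**2).mean() * w + 4 * constraint_weight * P[:, c]
                w_new /= max(np.linalg.norm(w_new), 1e-12)
                if w_new @ P[:, c] < 0:
                    w_new = -w_new
                delta = 1 - abs(w_new @ w)
                w = w_new
                if delta < tol:
                    break
            W[:, c] = w
            converged[c] = False
    maps = np.zeros((V, C))
    maps[mask] = _zscore_cols(Y @ W)
    # time-courses by adaptive ridge regression of the data on the subject
    # maps: denoised maps can be nearly collinear (the mean direction is
    # removed by centering), so the ridge is scaled by the residual-variance
    # fraction — zero for an exact mixture, substantial under heavy noise
    Mm = maps[mask]
    G = Mm.T @ Mm / Vm
    b = Mm.T @ Xc / Vm
    tc_ols = np.linalg.lstsq(Mm, Xc, rcond=None)[0]
    resid_frac = float(np.var(Xc - Mm @ tc_ols) / max(np.var(Xc), 1e-300))
    eps = 0.05 * resid_frac * np.trace(G) / C
    tc = np.linalg.solve(G + eps * np.eye(C), b).T  # T x C
    tc = _zscore_cols(tc)
    spatial_corr = np.array(
        [_corr_cols(maps[mask][:, [c]], refs_z[:, [c]])[0, 0] for c in range(C)]
    )
    flip = spatial_corr < 0
    maps[:, flip] *= -1
    tc[:, flip] *= -1
    spatial_corr = np.abs(spatial_corr)
    return SubjectDecomposition(
        maps=maps, tc=tc, spatial_corr=spatial_corr, method="constrained_ica", converged=converged
    )


def load_nifti_maps(path: str) -> tuple[np.ndarray, tuple]:
    """Load a 3D/4D NIfTI as a voxels x volumes matrix plus the 3D shape."""
    import nibabel as nib

    img = nib.load(path)
    arr = np.asarray(img.dataobj, dtype=float)
    if arr.ndim == 3:
        arr = arr[..., None]
    shape3 = arr.shape[:3]
    return arr.reshape(-1, arr.shape[3]), shape3


def save_nifti_maps(matrix: np.ndarray, shape3: tuple, path: str, affine=None) -> None:
    """Save a voxels x components matrix as a 4D NIfTI volume."""
    import nibabel as nib

    if affine is None:
        affine = np.eye(4)
    vol = np.asarray(matrix).reshape(*shape3, -1)
    nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), path)
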