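"""Head-motion indices, subject-level QC, and time-course cleaning.

Implements the four-level motion handling scheme of the emulated study:
absolute displacement/rotation cut-offs, a mean framewise-displacement (FD)
cut-off, 12-parameter nuisance regression of the network time-courses, and
FD as a group-level nuisance covariate (the last lives in :mod:`.stats`).

FD follows the Power convention: per-frame sum of absolute backward
differences of the six realignment parameters, with rotations (radians)
converted to arc length on a 50 mm sphere.

The cleaning chain applied to component time-courses is fixed:
detrend -> 12-parameter nuisance regression -> despike -> 5th-order
Butterworth band-pass (0.01-0.15 Hz) -> z-score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

__all__ = [
    "MotionSummary",
    "QcDecision",
    "compute_fd_power",
    "apply_motion_exclusion",
    "detrend_timecourse",
    "regress_nuisance",
    "despike",
    "bandpass_butterworth",
    "zscore",
    "clean_timecourses",
]


@dataclass(frozen=True)
class MotionSummary:
    fd: np.ndarray  # length-T, mm; fd[0] = 0
    mean_fd: float  # mm
    max_abs_translation: float  # mm
    max_abs_rotation: float  # degrees
    n_fd_gt_0p5: int
    frac_fd_gt_0p5: float


@dataclass(frozen=True)
class QcDecision:
    included: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)


def compute_fd_power(motion: np.ndarray, head_radius: float = 50.0) -> MotionSummary:
    """Framewise displacement (Power) from a T x 6 realignment trace.

    Columns are ordered translations (mm) then rotations (radians). Rotation
    differences are expressed as arc length on a sphere of ``head_radius`` mm.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion trace must be T x 6, got {motion.shape}")
    T = motion.shape[0]
    if T < 2:
        raise ValueError("motion trace must have T >= 2 frames")
    d = np.abs(np.diff(motion, axis=0))
    fd = np.concatenate(([0.0], d[:, :3].sum(axis=1) + head_radius * d[:, 3:].sum(axis=1)))
    n_gt = int(np.sum(fd > 0.5))
    return MotionSummary(
        fd=fd,
        mean_fd=float(fd.mean()),
        max_abs_translation=float(np.abs(motion[:, :3]).max()),
        max_abs_rotation=float(np.degrees(np.abs(motion[:, 3:]).max())),
        n_fd_gt_0p5=n_gt,
        frac_fd_gt_0p5=n_gt / T,
    )


def apply_motion_exclusion(
    summary: MotionSummary,
    abs_trans_mm: float = 2.5,
    abs_rot_deg: float = 2.5,
    mean_fd_mm: float = 0.2,
) -> QcDecision:
    """Subject-level exclusion by the absolute and relative motion cut-offs.

    A subject is excluded iff max |translation| > 2.5 mm, or max |rotation|
    > 2.5 degrees, or mean FD > 0.2 mm. All cut-offs are strict: a subject
    sitting exactly on a boundary is retained.
    """
    reasons: list[str] = []
    if summary.max_abs_translation > abs_trans_mm:
        reasons.append("absolute_translation")
    if summary.max_abs_rotation > abs_rot_deg:
        reasons.append("absolute_rotation")
    if summary.mean_fd > mean_fd_mm:
        reasons.append("relative_fd")
    return QcDecision(included=not reasons, reasons=tuple(reasons))


def _as_2d(tc: np.ndarray) -> tuple[np.ndarray, bool]:
    tc = np.asarray(tc, dtype=float)
    if tc.ndim == 1:
        return tc[:, None], True
    if tc.ndim != 2:
        raise ValueError("time-courses must be 1-D or 2-D")
    return tc, False


def detrend_timecourse(tc: np.ndarray) -> np.ndarray:
    """Remove the least-squares linear trend (intercept + slope) per column."""
    X, squeeze = _as_2d(tc)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 time points to detrend")
    out = sps.detrend(X, axis=0, type="linear")
    return out[:, 0] if squeeze else out


def regress_nuisance(tc: np.ndarray, motion: np.ndarray) -> np.ndarray:
    """Orthogonalize time-courses to the 12-parameter motion design.

    The design holds an intercept, the six realignment parameters, and their
    first-order backward differences (first row zero). Residuals are computed
    by least squares with a pseudoinverse, so a rank-deficient design (e.g. an
    all-zero motion trace) degrades gracefully instead of raising.
    """
    X, squeeze = _as_2d(tc)
    motion = np.asarray(motion, dtype=float)
    if motion.shape != (X.shape[0], 6):
        raise ValueError(f"motion must be {X.shape[0]} x 6, got {motion.shape}")
    deriv = np.vstack([np.zeros(6), np.diff(motion, axis=0)])
    design = np.column_stack([np.ones(X.shape[0]), motion, deriv])
    beta = np.linalg.pinv(design) @ X
    resid = X - design @ beta
    return resid[:, 0] if squeeze else resid


def despike(tc: np.ndarray, z_thresh: float = 3.5) -> np.ndarray:
    """Replace outlier time points by cubic-spline interpolation.

    Outliers are detected by robust z-score, |x - median| / (1.4826 * MAD),
    exceeding ``z_thresh``. Flagged points are replaced by a 3rd-order spline
    fitted to the non-flagged points; non-flagged points are untouched.
    """
    x = np.asarray(tc, dtype=float)
    if x.ndim != 1:
        raise ValueError("despike operates on a single time-course")
    if x.size < 8:
        raise ValueError("need at least 8 time points to despike")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    dev = np.abs(x - med)
    if mad > 0:
        z = dev / (1.4826 * mad)
    else:
        z = np.where(dev > 0, np.inf, 0.0)
    flagged = z > z_thresh
    if flagged.all():
        raise ValueError("all time points flagged as outliers: degenerate signal")
    if not flagged.any():
        return x.copy()
    idx = np.arange(x.size)
    spline = CubicSpline(idx[~flagged], x[~flagged], extrapolate=True)
    out = x.copy()
    out[flagged] = spline(idx[flagged])
    return out


def bandpass_butterworth(
    tc: np.ndarray,
    TR: float,
    low: float = 0.01,
    high: float = 0.15,
    order: int = 5,
) -> np.ndarray:
    """Zero-phase band-pass with a 5th-order Butterworth filter.

    Applied forward-backward (``sosfiltfilt``) so window timing is not phase
    shifted; second-order sections keep the order-5 band-pass numerically
    stable.
    """
    X, squeeze = _as_2d(tc)
    fs = 1.0 / TR
    nyq = fs / 2.0
    if high >= nyq:
        raise ValueError(f"high cut-off {high} Hz must be below Nyquist {nyq} Hz")
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    out = sps.sosfiltfilt(sos, X, axis=0)
    return out[:, 0] if squeeze else out


def zscore(tc: np.ndarray) -> np.ndarray:
    """Standardize each column to mean 0 and (population) SD 1."""
    X, squeeze = _as_2d(tc)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance column(s): {bad.tolist()}")
    out = (X - mu) / sd
    return out[:, 0] if squeeze else out


def clean_timecourses(
    tc: np.ndarray,
    motion: np.ndarray,
    TR: float,
    low: float = 0.01,
    high: float = 0.15,
    order: int = 5,
    z_thresh: float = 3.5,
) -> np.ndarray:
    """Run the fixed cleaning chain on a T x C time-course matrix."""
    X = detrend_timecourse(tc)
    X = regress_nuisance(X, motion)
    X = np.column_stack([despike(X[:, c], z_thresh=z_thresh) for c in range(X.shape[1])])
    X = bandpass_butterworth(X, TR, low=low, high=high, order=order)
    return zscore(X)
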