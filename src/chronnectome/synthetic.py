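"""Synthetic two-group cohort generator with known switching connectivity.

The generator emulates the study design the package is built around: two
groups of resting-state subjects (defaults 18 vs 20), each providing a
network-component time-course matrix (200 volumes at TR = 2 s across 37
components) plus a 6-parameter realignment trace. The latent model is a
first-order Markov chain over a small set of ground-truth connectivity
patterns (CPs): at each TR the C-dimensional observation is drawn from a
zero-mean multivariate normal whose covariance is the correlation matrix of
the currently occupied pattern, plus white observation noise. One group
switches patterns more often than the other, so downstream meta-state
fluidity metrics have a planted, recoverable group effect.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .motion import compute_fd_power

__all__ = [
    "GroundTruthCP",
    "StateSequence",
    "CohortConfig",
    "SubjectRecord",
    "Cohort",
    "generate_cp_matrices",
    "generate_state_sequence",
    "generate_timecourses",
    "generate_motion",
    "generate_cohort",
    "nearest_correlation",
]


@dataclass(frozen=True)
class GroundTruthCP:
    """A ground-truth connectivity pattern: a valid C x C correlation matrix."""

    pattern_id: int
    correlation_matrix: np.ndarray

    def validate(self) -> None:
        R = self.correlation_matrix
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("correlation_matrix must be square")
        if not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("correlation_matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-10):
            raise ValueError("correlation_matrix must have unit diagonal")
        if np.any(np.abs(R) > 1 + 1e-10):
            raise ValueError("correlations must lie in [-1, 1]")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ValueError("correlation_matrix must be positive semi-definite")


@dataclass(frozen=True)
class StateSequence:
    """Latent pattern labels over time, values in {1..k_true}."""

    labels: np.ndarray  # length-T integer vector

    @property
    def dwell_times(self) -> np.ndarray:
        """Run lengths (in TR) of consecutive identical labels."""
        lab = self.labels
        if lab.size == 0:
            return np.array([], dtype=int)
        change = np.flatnonzero(np.diff(lab) != 0)
        bounds = np.concatenate(([-1], change, [lab.size - 1]))
        return np.diff(bounds)

    def validate(self, k_true: int) -> None:
        if self.labels.size < 1:
            raise ValueError("state sequence must have length >= 1")
        if self.labels.min() < 1 or self.labels.max() > k_true:
            raise ValueError(f"labels must lie in 1..{k_true}")


@dataclass
class CohortConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults follow the emulated study: 18 experts vs 20 novices, 200 volumes
    at TR = 2 s, 37 network components, 5 latent connectivity patterns, group
    mean framewise displacement 0.14 vs 0.16 mm, and female proportions
    27.8% vs 65.0%. Switch rates (per-TR probability of leaving the current
    pattern) of 0.10 vs 0.02 plant the group difference in dynamism.
    """

    n_group_a: int = 18
    n_group_b: int = 20
    C: int = 37
    T: int = 200
    TR: float = 2.0
    k_true: int = 5
    switch_rate_a: float = 0.10
    switch_rate_b: float = 0.02
    noise_sd: float = 0.5
    mean_fd_a: float = 0.14
    mean_fd_b: float = 0.16
    fd_sd_a: float = 0.04
    fd_sd_b: float = 0.04
    female_p_a: float = 0.278
    female_p_b: float = 0.650
    group_names: tuple[str, str] = ("expert", "novice")
    seed: int = 0

    def validate(self) -> None:
        if self.n_group_a < 1 or self.n_group_b < 1:
            raise ValueError("group sizes must be >= 1")
        if self.C < 2:
            raise ValueError("C must be >= 2")
        if self.T < 2:
            raise ValueError("T must be >= 2")
        if self.TR <= 0:
            raise ValueError("TR must be positive")
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        for r in (self.switch_rate_a, self.switch_rate_b):
            if not 0.0 <= r <= 1.0:
                raise ValueError("switch rates must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.mean_fd_a < 0 or self.mean_fd_b < 0:
            raise ValueError("mean FD targets must be >= 0")
        if self.fd_sd_a < 0 or self.fd_sd_b < 0:
            raise ValueError("FD spreads must be >= 0")
        for p in (self.female_p_a, self.female_p_b):
            if not 0.0 <= p <= 1.0:
                raise ValueError("female proportions must lie in [0, 1]")


@dataclass
class SubjectRecord:
    """One simulated subject plus its retained ground truth."""

    subject_id: str
    group: str
    gender: str  # "F" or "M"
    tc: np.ndarray  # T x C
    motion: np.ndarray  # T x 6
    TR: float
    states: StateSequence


@dataclass
class Cohort:
    """A simulated multi-subject cohort with shared ground-truth CPs."""

    config: CohortConfig
    cps: list[GroundTruthCP]
    subjects: list[SubjectRecord] = field(default_factory=list)


def nearest_correlation(A: np.ndarray, tol: float = 1e-8, max_iter: int = 200) -> np.ndarray:
    """Project a symmetric matrix to the nearest correlation matrix.

    Higham's alternating-projection algorithm with Dykstra correction:
    alternately project onto the positive semi-definite cone and onto the set
    of unit-diagonal symmetric matrices until the iterate moves less than
    ``tol`` in Frobenius norm.
    """
    Y = np.asarray(A, dtype=float).copy()
    dS = np.zeros_like(Y)
    for _ in range(max_iter):
        R = Y - dS
        # PSD projection
        w, V = np.linalg.eigh((R + R.T) / 2)
        X = (V * np.clip(w, 0, None)) @ V.T
        dS = X - R
        Y_new = X.copy()
        np.fill_diagonal(Y_new, 1.0)
        if np.linalg.norm(Y_new - Y, "fro") < tol:
            Y = Y_new
            break
        Y = Y_new
    # final PSD cleanup: clip tiny negative eigenvalues, restore unit diagonal
    w, V = np.linalg.eigh((Y + Y.T) / 2)
    Y = (V * np.clip(w, 0, None)) @ V.T
    d = np.sqrt(np.clip(np.diag(Y), 1e-12, None))
    Y = Y / np.outer(d, d)
    np.fill_diagonal(Y, 1.0)
    return np.clip((Y + Y.T) / 2, -1.0, 1.0)


def _pattern_correlation(R1: np.ndarray, R2: np.ndarray) -> float:
    iu = np.triu_indices_from(R1, k=1)
    a, b = R1[iu], R2[iu]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    return float(a @ b / denom) if denom > 0 else 0.0


def generate_cp_matrices(C: int, k_true: int, seed: int) -> list[GroundTruthCP]:
    """Draw ``k_true`` distinct block-structured correlation matrices.

    Each pattern elevates within-block correlation (uniform in [0.5, 0.8]) for
    a different block of components, with weak off-block correlation (uniform
    in [-0.2, 0.2]); the raw matrix is then projected to the nearest valid
    correlation matrix. Patterns are redrawn until every pair has
    off-diagonal pattern correlation below 0.5.
    """
    if C < 2:
        raise ValueError("C must be >= 2")
    if k_true < 1:
        raise ValueError("k_true must be >= 1")
    rng = np.random.default_rng(seed)
    block_size = max(2, C // max(k_true, 2))
    for _attempt in range(50):
        order = rng.permutation(C)
        cps: list[GroundTruthCP] = []
        for pid in range(k_true):
            if (pid + 1) * block_size <= C:
                block = order[pid * block_size : (pid + 1) * block_size]
            else:  # more patterns than disjoint blocks fit: draw a fresh block
                block = rng.choice(C, size=block_size, replace=False)
            R = rng.uniform(-0.2, 0.2, size=(C, C))
            R = (R + R.T) / 2
            within = rng.uniform(0.5, 0.8, size=(block.size, block.size))
            within = (within + within.T) / 2
            R[np.ix_(block, block)] = within
            np.fill_diagonal(R, 1.0)
            R = nearest_correlation(R, tol=1e-8)
            cp = GroundTruthCP(pattern_id=pid + 1, correlation_matrix=R)
            cp.validate()
            cps.append(cp)
        ok = all(
            abs(_pattern_correlation(cps[i].correlation_matrix, cps[j].correlation_matrix)) < 0.5
            for i in range(k_true)
            for j in range(i + 1, k_true)
        )
        if ok:
            return cps
    raise RuntimeError("could not generate sufficiently distinct CP matrices")


def generate_state_sequence(T: int, k_true: int, switch_rate: float, seed: int) -> StateSequence:
    """Simulate a first-order Markov label sequence over {1..k_true}.

    The first label is uniform; at each later TR the chain leaves its state
    with probability ``switch_rate``, jumping to a uniformly chosen different
    state.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if not 0.0 <= switch_rate <= 1.0:
        raise ValueError("switch_rate must lie in [0, 1]")
    if k_true < 1:
        raise ValueError("k_true must be >= 1")
    rng = np.random.default_rng(seed)
    labels = np.empty(T, dtype=int)
    labels[0] = rng.integers(1, k_true + 1)
    if k_true == 1:
        labels[:] = 1
        return StateSequence(labels=labels)
    jumps = rng.random(T - 1) < switch_rate
    for t in range(1, T):
        if jumps[t - 1]:
            # uniform over the k_true - 1 other states
            offset = rng.integers(1, k_true)
            labels[t] = 1 + (labels[t - 1] - 1 + offset) % k_true
        else:
            labels[t] = labels[t - 1]
    return StateSequence(labels=labels)


def _cov_sqrt(R: np.ndarray) -> np.ndarray:
    """Symmetric square root via eigendecomposition with eigenvalue clipping."""
    w, V = np.linalg.eigh(R)
    return V * np.sqrt(np.clip(w, 0, None))


def generate_timecourses(
    cps: list[GroundTruthCP],
    states: StateSequence,
    noise_sd: float,
    seed: int,
) -> np.ndarray:
    """Draw the T x C observation matrix implied by a state sequence.

    At TR ``t`` the row is multivariate normal with covariance equal to the
    correlation matrix of pattern ``states.labels[t]``, plus independent
    N(0, noise_sd^2) observation noise per component.
    """
    if not cps:
        raise ValueError("need at least one CP")
    C = cps[0].correlation_matrix.shape[0]
    if any(cp.correlation_matrix.shape != (C, C) for cp in cps):
        raise ValueError("all CPs must share dimension C")
    T = states.labels.size
    if T < 1:
        raise ValueError("state sequence must be non-empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    states.validate(k_true=len(cps))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((T, C))
    X = np.empty((T, C))
    for cp in cps:
        idx = np.flatnonzero(states.labels == cp.pattern_id)
        if idx.size:
            L = _cov_sqrt(cp.correlation_matrix)
            X[idx] = z[idx] @ L.T
    if noise_sd > 0:
        X += noise_sd * rng.standard_normal((T, C))
    return X


def generate_motion(T: int, target_mean_fd: float, seed: int, head_radius: float = 50.0) -> np.ndarray:
    """Simulate a 6-column realignment trace with a prescribed mean FD.

    A Gaussian random walk over 3 translations (mm) and 3 rotations (radians)
    is rescaled so that the Power framewise displacement of the trace has
    exactly the target mean (FD is homogeneous of degree one in the trace).
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    if target_mean_fd < 0:
        raise ValueError("target_mean_fd must be >= 0")
    if target_mean_fd == 0:
        return np.zeros((T, 6))
    rng = np.random.default_rng(seed)
    steps = np.empty((T - 1, 6))
    steps[:, :3] = rng.normal(0.0, 0.02, size=(T - 1, 3))  # mm
    steps[:, 3:] = rng.normal(0.0, 2e-4, size=(T - 1, 3))  # radians
    trace = np.vstack([np.zeros(6), np.cumsum(steps, axis=0)])
    mean_fd = compute_fd_power(trace, head_radius=head_radius).mean_fd
    trace *= target_mean_fd / mean_fd
    return trace


def generate_cohort(config: CohortConfig) -> Cohort:
    """Simulate the full two-group cohort, retaining all ground truth.

    All subjects share one set of ground-truth CPs (the group-level basis the
    downstream decomposition should recover); each subject gets its own state
    sequence (group-specific switch rate), time-courses, motion trace (group-
    specific mean FD) and gender label (group-specific female probability).
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    cp_seed, *subject_seeds = ss.spawn(1 + config.n_group_a + config.n_group_b)
    cps = generate_cp_matrices(config.C, config.k_true, seed=cp_seed)
    cohort = Cohort(config=replace(config), cps=cps)
    specs = [
        (config.group_names[0], config.switch_rate_a, config.mean_fd_a,
         config.fd_sd_a, config.female_p_a)
    ] * config.n_group_a + [
        (config.group_names[1], config.switch_rate_b, config.mean_fd_b,
         config.fd_sd_b, config.female_p_b)
    ] * config.n_group_b
    for i, ((group, switch_rate, mean_fd, fd_sd, female_p), sseed) in enumerate(
        zip(specs, subject_seeds)
    ):
        s_state, s_tc, s_mot, s_gender = sseed.spawn(4)
        states = generate_state_sequence(config.T, config.k_true, switch_rate, seed=s_state)
        tc = generate_timecourses(cps, states, config.noise_sd, seed=s_tc)
        # subject-level FD spread around the group mean keeps FD from being
        # collinear with group in the downstream GLM; capped below the 0.2 mm
        # QC cut-off because the emulated cohort is the post-QC sample
        fd_target = mean_fd
        if fd_sd > 0:
            fd_target = float(
                np.clip(np.random.default_rng(s_mot).normal(mean_fd, fd_sd), 0.01, 0.199)
            )
        motion = generate_motion(config.T, fd_target, seed=s_mot.spawn(1)[0])
        gender = "F" if np.random.default_rng(s_gender).random() < female_p else "M"
        cohort.subjects.append(
            SubjectRecord(
                subject_id=f"sub-{i + 1:03d}",
                group=group,
                gender=gender,
                tc=tc,
                motion=motion,
                TR=config.TR,
                states=states,
            )
        )
    if len(cohort.subjects) != config.n_group_a + config.n_group_b:
        warnings.warn("cohort size mismatch")  # pragma: no cover - defensive
    return cohort
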