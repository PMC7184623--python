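# Methods

This note documents the models, estimators and numerical choices behind the
package, and what its synthetic benchmark does and does not establish.

## The analysis

The pipeline quantifies whole-brain *dynamic* functional network
connectivity (dFNC) through the meta-state formalism. Starting from C
network-component time-courses per subject (here C = 37, T = 200 volumes at
TR = 2 s):

1. **Cleaning.** Each component time-course is detrended (linear),
   orthogonalized to the 12-parameter motion design (6 realignment
   parameters and their backward differences, first frame zero), despiked
   (robust-z outlier detection at 3.5 via median/MAD, replacement by a cubic
   spline through the clean points), band-passed with a zero-phase 5th-order
   Butterworth filter (0.01–0.15 Hz, second-order sections), and z-scored.
   The chain order is fixed.
2. **Windowed connectivity.** Windows of width 30 TR slide in steps of 1 TR
   (W = T − 30 + 1 = 171 full windows; no partial windows). Window weights
   are a rectangle convolved with a unit-area Gaussian of σ = 3 TR
   (kernel support ±4σ, truncated to the central 30 samples, normalized to
   sum 30; any positive rescaling is output-invariant). Within each window a
   taper-weighted covariance is normalized to a correlation matrix and
   regularized with the graphical lasso (off-diagonal L1 penalty on the
   precision, iteration budget 100); the fitted covariance is renormalized
   to unit diagonal. A 30-frame window cannot support an unregularized
   37 × 37 estimate, hence the penalty.
3. **λ selection.** One penalty per subject, chosen on a log-spaced
   10-point grid in [0.03, 1] by 5-fold cross-validation over windows: per
   fold the model is fitted to the mean training-window correlation and
   scored by the Gaussian log-likelihood of the held-out windows. The grid
   is first restricted to penalties at which *single* windows can be fitted
   (probed on a window subsample): the grid floor of 0.03 reflects where the
   coordinate-descent solver is reliable on rank-deficient 30-frame windows.
   On the synthetic cohort the criterion is monotone toward small penalties
   and the feasibility floor binds, which is the intended behavior: the
   penalty should be the smallest that stabilizes the per-window problem.
4. **Connectivity patterns.** The W × P windowed FNC rows of all subjects
   (P = C(C−1)/2 = 666 pairs) are stacked and decomposed by spatial ICA
   (FastICA, log-cosh contrast, deflation with a symmetric-update fallback,
   whitening to k components) into k = 5 CP loading rows over the pair
   axis; components are sign-fixed (largest-|loading| entry positive) and
   ordered by explained variance. Each subject's windows are regressed
   (OLS with intercept) on the CP basis, giving continuous k-dimensional
   CP-weight trajectories.
5. **Meta-states.** Weights are discretized per CP into eight signed
   quartile bins: quartile edges are computed separately over the positive
   values and over the magnitudes of the negative values of the pooled
   (all-subjects) weights, mapping to +1..+4 and −1..−4; exact zeros map to
   +1 and boundary ties fall to the lower bin. Pooling the reference across
   subjects ("group" binning, the default; "subject" binning is available)
   makes bins comparable across subjects. The discrete k-vector at each
   window is the subject's meta-state; with k = 5, the space holds
   8^5 = 32,768 states.
6. **Fluidity metrics.** Four scalars per subject: the number of distinct
   meta-states; the number of switches between successive meta-states; the
   span (largest L1 distance between two occupied states); and the total
   distance (summed L1 distance between successive states).
7. **Inference.** Each metric is modeled by OLS on [intercept, group,
   gender, mean FD]; the four group p-values (two-sided) are corrected
   together by Benjamini–Hochberg FDR (family size 4; the model-order sweep
   is reported uncorrected as a robustness view). Partial Pearson
   correlations (residualize-both, t reference with n − k − 2 df) relate the
   metrics to training time and education when those covariates exist.

Motion handling follows the four-level scheme: strict subject exclusion at
max |translation| > 2.5 mm, max |rotation| > 2.5°, or mean framewise
displacement > 0.2 mm; FD uses the Power convention (sum of absolute
backward differences of the six parameters, rotations as arc length on a
50 mm sphere — the radius is exposed as a parameter since the convention,
not the radius, is what the upstream literature fixes).

## The synthetic cohort

The generator emulates the study design the pipeline targets: two groups
(18 "experts" vs 20 "novices"), C = 37, T = 200, TR = 2 s. The latent model
is a first-order Markov chain over k_true = 5 pure connectivity patterns:
block correlation matrices (one block per pattern, within-block
correlations uniform in [0.5, 0.8], off-block in [−0.2, 0.2], projected to
the nearest valid correlation matrix by Higham alternating projection,
tolerance 1e−8, with redraws until all pattern pairs correlate below 0.5).
At each TR the observation is multivariate normal with the current
pattern's correlation as covariance (eigendecomposition square root,
eigenvalues clipped at 0) plus white noise of sd 0.5 — an observation-noise
level that attenuates correlations by ~20%, a middle ground between a
noiseless idealization and noise-dominated data. Experts switch patterns
with per-TR probability 0.10, novices 0.02.

Motion traces are Gaussian random walks over six parameters rescaled
exactly to a per-subject target mean FD; targets are drawn per subject as
N(group mean, 0.04) — the spread reported for the emulated cohort — and
clipped below the 0.2 mm cut-off because the emulated sample is the
*post-QC* cohort (without the spread, FD would be collinear with group in
the GLM). Gender is Bernoulli per group (27.8% vs 65.0% female). Every
generator is deterministic given its seed; the cohort seed fans out to
per-subject streams via `SeedSequence.spawn`.

## What the benchmark shows — and a fixture limitation

On the default cohort the pipeline recovers the five planted patterns with
mean matched |correlation| ≈ 0.92, produces occupancy in the right regime
(mean occupied states ≈ 0.2–0.3% of the 32,768-state space), and the group
GLM is correctly calibrated under the null (type-I error ≈ 0.05 per metric
over 200 replicate cohorts).

The planted *group difference* in fluidity, however, does not survive
windowed estimation under this latent model, and this is worth
understanding before trusting any pure-Markov fixture for power analyses.
In the estimation-free limit (CP weights replaced by exact taper-weighted
state fractions) the fast-switching group dominates every fluidity metric
by a wide margin. With honest 30-frame windowed estimates, the slow group's
long pure-state plateaus concentrate probability mass exactly where the
pooled quartile boundaries fall; window-to-window estimation jitter (median
adjacent-window weight step ~0.008 against bin widths ~0.1) then makes
plateau windows flicker between adjacent bins. This inflates the slow
group's state counts and distances far more than the fast group's, erasing
— at some penalties reversing — the planted ordering. Real resting-state
weight trajectories do not sit in pure states, so this boundary-flicker
pathology is a property of the pure-CP Markov fixture, not of the
estimator; the group means and dispersions the pipeline produces are
otherwise in the regime reported for real cohorts. A fixture intended to
demonstrate group *power* (rather than calibration and recovery) would need
a latent process without long exact plateaus, e.g. smoothly mixing CP
weights.

## Numerical choices

- Graphical lasso: scikit-learn's coordinate-descent solver, warm-started
  across overlapping windows (29/30 shared frames); a fitted covariance is
  rejected and refitted cold if it is non-finite or implies |r| ≥ 1
  (warm-start poisoning is rare but real). Solver duality-gap tolerance
  defaults to 1e−3 — estimates move by less than ~5e−3, far below 30-frame
  sampling noise, at ~12× less cost; it is a parameter where tighter
  agreement is needed. λ = 0 returns the weighted sample correlation
  exactly (the unpenalized limit) and errors on zero-variance components;
  at λ > 0 a zero-variance component is floored so the solver runs and its
  off-diagonals shrink to zero.
- FastICA: deflation first (symmetric updates oscillate on stacked FNC at
  some scales), with two retry seeds and a symmetric-algorithm fallback;
  duplicate/degenerate source sets are treated as non-convergence.
- Spatially constrained ICA (optional voxel stage): one-unit log-cosh
  fixed-point updates in a C-component spatial-PCA whitening, anchored to
  each z-scored reference map by the constant-gradient closeness term, and
  initialized from dual regression (`max_iter=0` returns the dual-regression
  solution). Components that drift closer to a foreign reference are
  re-anchored with a 4× constraint. Subject time-courses come from an
  adaptive ridge regression of the data on the subject maps: the ridge
  scales with the residual-variance fraction, so an exact mixture is solved
  exactly while noisy, nearly-collinear maps (centering removes the mean
  direction) are stabilized.
- Quartile edges use linear-interpolation percentiles; values equal to an
  edge take the lower bin; exact zeros take +1.
- Reduced designs in the test-bench (e.g. the null-calibration study at
  n = 10+10, C = 10, T = 120, λ = 0) keep windows well-conditioned so the
  unpenalized path is exact; the quantity under test — GLM calibration on
  pipeline-derived metrics — is unchanged by the penalty setting.

## Known limitations

- The voxel-level stage is exercised on synthetic mixtures only; no
  hemodynamics, spatial autocorrelation, or scanner artifacts beyond the
  motion trace are simulated.
- The windowed-FNC edge policy (full windows only, first window at frame 0)
  and the iteration-budget reading of the solver's "repetitions" are
  package conventions, recorded in the run manifest.
- Group-difference power under the pure-Markov fixture is limited by the
  plateau/boundary interaction described above; conclusions about real-data
  sensitivity should not be drawn from it.
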