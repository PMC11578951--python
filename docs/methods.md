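# Methods

## The control-theoretic model

Brain activity is modelled as a noise-free, linear, discrete-time,
time-invariant system

    x_{t+1} = A x_t + B_K u_K(t),

with `x ∈ R^N` (N = 90 AAL nodes) the BOLD state, `A` a weighted symmetric
adjacency derived from functional connectivity, `B_K` the input matrix
selecting the control set `K`, and `u_K(t)` the exogenous input. Following
the convention of functional (as opposed to structural) controllability
work, `A` comes from the Pearson FC matrix of a session. Node-wise metrics
use every node as a *single* control point in turn (|K| = 1):

* **Average controllability** `AC_i = trace(W_K)` with
  `W_K = Σ_{τ=0}^{∞} A^τ B_K B_Kᵀ A^τ`. For symmetric Schur-stable `A`
  with eigenpairs `(λ_j, v_j)` this reduces to
  `AC_i = Σ_j v_ij² / (1 − λ_j²)`. The τ = 0 term is `B_KᵀB_K = 1`, so
  `AC_i ≥ 1` always. High-AC nodes reach nearby states cheaply.
* **Modal controllability** `φ_i = Σ_j (1 − λ_j²) v_ij²`, in `(0, 1]` for
  spectral radius < 1 (row normalization `Σ_j v_ij² = 1` gives
  `φ_i = 1 − Σ_j λ_j² v_ij²`). High-MC nodes steer the system into
  fast-decaying, hard-to-reach modes.

The input `u_K(t)` and trajectory `x_t` appear only in the model statement;
no control trajectory is materialized.

**Stabilization.** An FC matrix is not Schur-stable, so the infinite
Gramian sum would diverge. We adopt `A = c·C / (1 + σ_max(C))` with
`c = 1` by default (configurable `c < 1` for extra shrinkage), `σ_max` the
largest singular value. The diagonal of `C` is zeroed before stabilization
so self-loops cannot inflate controllability, correlations are *not*
Fisher-z transformed, and numerically asymmetric inputs are symmetrized as
`(C + Cᵀ)/2` with a warning (asymmetry beyond 1e-6 is an error). Since `A`
is symmetric its eigenvalues are real and `λ_j²` is unambiguous; one
eigendecomposition per session serves all 90 nodes.

**Verification.** The closed-form AC is checked against two independent
oracles — a discrete-Lyapunov solve of `A W Aᵀ − W = −B Bᵀ` and the
truncated power sum with tail bound `ρ^{2T}/(1 − ρ²) < 1e−10` — agreeing
within 1e-8 on random stabilized matrices up to 90 × 90.

**Delta controllability** is fixed as on − off (medication-on minus
medication-off); all downstream correlation signs follow this convention.

## Signal processing

Sessions are T × N tables at TR = 2 s (223 retained frames by default).
The default order is: linear detrend + ideal frequency-domain band-pass
(0.01–0.08 Hz, inclusive bins), then confound regression, then scrubbing,
then Pearson FC. Choices:

* *Filter*: ideal (boxcar in frequency) by default; 4th-order Butterworth
  `filtfilt` behind `filter_method="butterworth"`. Output length equals
  input length.
* *Confounds*: the session-mean (global) signal plus the Friston-24 motion
  expansion `[p, p_lag, p², p_lag²]` of the six rigid-body parameters; an
  intercept is always added and linearly dependent columns are dropped with
  a warning. With filtering first, the confounds are passed through the
  same filter so regression cannot reintroduce out-of-band energy; the
  reverse order is available via `order="regress_then_filter"` since
  published pipelines disagree here.
* *Scrubbing*: Power-style framewise displacement
  `FD_t = Σ|Δtrans| + 50 mm · Σ|Δrot|`, threshold 0.5 mm, removing each
  offending frame plus the one after it; a session losing more than half
  its frames is flagged unusable. All three values are configurable.
* *FC*: pairwise Pearson correlation, diagonal set to 0 afterward;
  zero-variance nodes yield zero correlations with a warning instead of
  NaNs.

## Synthetic cohort

The generator emulates the *structure* of a two-target DBS study: 24 STN
and 15 GPi patients with medication-off and -on sessions, 29 single-session
healthy controls, demographics drawn to match typical advanced-PD cohort
magnitudes (patients ≈ 59 ± 10 y, controls ≈ 53 ± 8 y, sex ratios per
stratum), preoperative UPDRS-III ≈ 56 ± 16, and a mean improvement anchor
of 68.65%.

* **Base network**: modular covariance (6 contiguous communities of 15
  nodes; within-block 0.6, between-block 0.1, unit variances with ±0.1
  seeded jitter, diagonal loading to keep the smallest eigenvalue ≥ 0.1).
* **Disease**: off-diagonal rows/columns of the designated disease nodes
  (caudate, putamen, pallidum, thalamus, precentral and postcentral gyri,
  both hemispheres) are attenuated by `perturbation_scale` (default 0.3 —
  chosen so the realized group effect at those nodes is well above 0.8 SD
  at 223 frames). Attenuation lowers AC and raises MC at those nodes, the
  qualitative disease pattern the screen must recover.
* **Medication**: each patient draws a recovery fraction from a Beta
  distribution with mean 0.5 and concentration 2 (≈ uniform — the
  distribution of medication response is a free design choice, not an
  inference); the on-session covariance is the convex combination
  `(1 − recovery)·off + recovery·base`.
* **Outcome**: percent improvement = intercept + 40·recovery + N(0, 5),
  truncated to [0, 100], with the intercept anchoring the mean at 68.65%.
  The postoperative score is backed out from the preoperative score so the
  improvement-rate identity holds exactly. Crucially, the outcome is linked
  to the *latent* recovery fraction, not to measured delta controllability,
  so the pipeline must recover the association through its own noisy
  estimates.
* **Missingness**: 5 on-sessions and 2 off-sessions (disjoint patients)
  are dropped by default to emulate motion-related scan exclusions.
* **Time series**: stationary Gaussian draws with the session covariance
  and AR(1) temporal autocorrelation φ = 0.3
  (`x_t = φ x_{t−1} + √(1−φ²) L z_t`); motion traces are a slow random
  walk with occasional 1 mm spikes so scrubbing has work to do.

What the generator does *not* emulate: hemodynamics, spatial structure,
nonstationarity, realistic motion artefacts coupled into the signal, or
non-Gaussian BOLD noise. Passing tests therefore demonstrate that the
pipeline recovers planted effects under its own model assumptions, not
that those assumptions hold for real scanner data.

## Statistical cascade

* Demographic comparisons use the conventions that reproduce standard
  cohort tables: pooled-variance two-sample t (|t| reported) and Pearson
  chi-square without continuity correction.
* The region screen fits `metric ~ group + age + sex` per region × metric
  (patients-off vs controls; age and sex are the two covariates that
  typically differ between such groups) and a paired t-test (on − off) over
  patients with both sessions; a region is **responsive** when both p-values
  fall below α = 0.05, uncorrected. No multiple-comparison correction is
  applied by default (an FDR switch exists), matching the uncorrected
  reporting convention of screening tables; the type-I cost is measured
  explicitly in the acceptance experiments. A vectorized OLS implementation
  handles the 180-cell grid; it is cross-checked against the statsmodels
  single-region route in the tests.
* Delta-outcome correlations cover eight a-priori motor structures ×
  2 hemispheres × 2 metrics (32 tests per surgical group), Pearson r with
  two-sided p, again uncorrected.

## Outcome prediction

Epsilon-SVR (RBF kernel, C = 1, ε = 0.1, γ = 1/n_features — the LIBSVM
defaults; hyperparameters are recorded in every result) over the group's
a-priori delta-controllability features: bilateral thalamic ΔAC for STN;
bilateral postcentral ΔAC, left postcentral ΔMC and left caudate ΔMC for
GPi. Under leave-one-subject-out cross-validation each fold standardizes
features *and* outcome using training-fold statistics only (SVR is
scale-sensitive, and C = 1 on a 0–100 percent scale would clamp the model
to a near-constant). The solver tolerance is tightened to 1e-6 so
predictions are independent of subject ordering.

**Evaluation.** Performance is the Pearson correlation between the model's
fold-standardized output and the actual improvements, with p from the
correlation t-test (df = n − 2) or an outcome-permutation null. The
standardized output is used deliberately: mapping predictions back through
the training-fold mean adds a `−y_i/(n−1)` mean-reversion term to every
LOOCV prediction, which biases the predicted-vs-actual correlation to
about −0.12 at n = 24 on pure-noise features; the standardized output
removes that artefact (measured null mean ≈ −0.01). A smaller residual
negative bias (order −0.02 to −0.06, dataset-dependent) remains because
permutation without replacement makes each held-out label anti-correlate
with the training-fold labels — any predictor that tracks a local training
mean inherits it. Percent-scale per-fold predictions are still reported
per subject for interpretability.

## Validation experiment sizes

The acceptance experiments run at desk scale, chosen to give stable
estimates while keeping a full run in minutes: 100 matrices (up to 90
nodes) for oracle agreement; 10⁴ randomized networks (2–60 nodes) for the
AC/MC bounds; 50 synthetic replicates each for screening sensitivity
(default planted effect) and type-I error (perturbation switched off);
a 4-point planted-link ladder (slopes 0/10/25/100 %-per-recovery-unit at
fixed 8% outcome noise, bimodal recovery Beta(0.25, 0.25), perturbation
0.1, complete sessions so the STN group is the full n = 24) × 20
replicates for the prediction strength curve; and 500 permutation refits
for the null. The strong end of the ladder realizes mean LOOCV r ≈ 0.55;
the weak end is indistinguishable from the permutation null.

## Known limitations

* The linear noise-free model is a deliberate reduction; controllability
  values describe the surrogate dynamics, not measured neural control.
* Stabilization by `1/(1 + σ_max)` is one of several conventions; absolute
  AC/MC values depend on it (rankings are less sensitive).
* The ANCOVA screen assumes Gaussian residuals and homogeneous covariate
  effects; the uncorrected α is a reporting convention, not an error-rate
  guarantee.
* GPi-group predictions (n = 15 before exclusions) are noisy at realistic
  planted effects; the synthetic experiments therefore quantify the STN
  configuration.
* Pipeline-order variants (regress-then-filter, no scrubbing, Butterworth)
  are supported but only the default path is exercised by the acceptance
  experiments.
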