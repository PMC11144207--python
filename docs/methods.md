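# Methods

## Ventilation model

The quantity of interest is the local volume-change ratio of the breathing
deformation φ(x) = x + u(x), where u is the displacement field (mm, world
axes) defined on the fixed-phase grid and mapping fixed-grid points to
their moving-phase locations. The ventilation surrogate is the Jacobian
determinant

    J(x) = det(I + ∂u/∂x),

computed with spacing-aware central differences in the grid interior and
one-sided differences at the borders. This scheme is exact for affine
fields (the basis of the closed-form tests). J > 1 marks expansion during
inhalation; the high-function lung (fLung) is the set of lung voxels with
J strictly greater than a threshold, default 1.2. The threshold applies to
the raw Jacobian — not to a lung-mean-normalized value — and no smoothing
is applied before thresholding unless the optional Gaussian pre-smoothing
(sigma in mm) is requested. Voxels with J ≤ 0 (local folding) are
physically implausible; they are retained in the map and counted in a log
message, and can never enter the fLung at positive thresholds.

## Displacement sources and registration

Any smooth displacement field can feed the ventilation stage; registration
is deliberately pluggable. The bundled reference is a multi-resolution
diffusive demons registration (SimpleITK's demons update, Gaussian field
smoothing each iteration) on a shrink-factor pyramid 2^(L−1) … 1. Levels
coarser than 4 voxels along the smallest axis are dropped. The field
smoothing request is given in mm and converted to voxels per level with a
floor of one voxel, below which the demons update field is too rough and
the iteration diverges. Each level runs a fixed iteration budget — no
convergence test — so registration is deterministic. If the final field
fails to reduce the mean squared intensity difference relative to the
identity, the zero field is returned with a warning; constant-intensity
inputs (no gradient to drive the update) return the zero field immediately.

Warping uses trilinear interpolation at x + u(x) with nearest-edge values
outside the moving grid, and is linear in image intensities.

The two extreme phases (peak exhale, peak inhale) are registered as a
single pair. Composing adjacent-phase fields across a 10-phase cine series
would be a straightforward extension but is not implemented.

## Breathing phantom

The phantom makes every stage testable against analytic ground truth.

* **Geometry.** Two ellipsoidal lungs inside a soft-tissue body ellipsoid;
  the exhale intensity is a smooth (sigmoid-edged) HU-like function:
  air −1000, body ≈ −50, lung ≈ −870, with a low-amplitude sinusoidal
  texture inside the lungs so that intensity-based registration has
  gradients to work with. Units are arbitrary; nothing downstream
  interprets absolute HU.
* **Motion.** Craniocaudally dominant displacement
  u_z = A · w(x)w(y)w(z) · exp(−κ·t), where t ∈ [0,1] is normalized height
  above the diaphragm end of the motion support, κ is the dimensionless
  decay rate (default 2), and w are C¹ cosine windows confining the motion
  to a bounded box around the lungs (lung bounding box plus a 15% margin,
  30% ramps). A is the peak diaphragm-level displacement, default 15 mm —
  deep tidal breathing. ∂u_z/∂z is available in closed form, so the exact
  Jacobian 1 + ∂u_z/∂z of the default phantom is computable analytically.
* **Affine mode** replaces the breathing model by u(x) = A·(x − c) with a
  constant matrix A, giving the spatially constant Jacobian det(I + A) —
  the main oracle for the ventilation stage.
* **Exact warping.** The inhale volume is the analytic exhale intensity
  evaluated at x + u(x); no interpolation enters the ground truth, so the
  truth-field/warp consistency test isolates the warper's interpolation
  error. Optional Gaussian intensity noise (default SD 10) is drawn
  independently per phase from a seeded generator.
* **Dose.** A Gaussian-falloff dose, prescription at the target and
  exp(−r²/2σ²) decay, whose total integral has the closed form
  Rx·(2π)^{3/2}σ³ used as an oracle.

What the phantom does **not** emulate: CT texture and noise statistics,
10-phase cine reconstruction, breathing irregularity, imaging artifacts,
sliding motion at the pleura, and hysteresis. Passing tests therefore
demonstrate correctness of the computational chain, not clinical accuracy
of demons registration on real 4D-CT.

## Cohort simulator

Each patient's covariate vector (V5…V60, percent) is drawn from a
multivariate normal, clipped to [0, 100], and sorted in descending order
within the row so that every draw is a valid cumulative DVH vector. The
default correlation is AR(1) with ρ = 0.9 and SD 15 — neighbouring dose
levels of a cumulative DVH are strongly collinear, and preserving that
multicollinearity is what makes the four selectors disagree at realistic
sample sizes. Default means fall from 72% (V5) to 2% (V60); the V25 mean
(41.3) is placed so that the linear predictor of the default generating
model at the mean covariates sits near logit(16/41) ≈ −0.45, the grade-≥2
pneumonitis prevalence of the reference cohort. Because the linear
predictor has substantial between-patient spread (SD ≈ 1.8), the realized
prevalence is nearer 0.5 — the expectation of a sigmoid is not the sigmoid
of the expectation. Outcomes are Bernoulli with probability
sigmoid(linear predictor) under the default generating model, the
published six-covariate stepwise formula. The default sample size is 41,
the reference study's size; every stochastic operation takes an explicit
seed (default 20240601).

The simulator draws covariates from a stated parametric family; it does
not estimate, and cannot reproduce, the covariate distribution of the
reference study's patients.

## Dose-volume computation

Vx is the *relative* volume — percent of the structure receiving ≥ x Gy,
inclusive — computed by exact voxel counting with uniform voxel volume (no
partial-volume weighting): determinism and oracle-testability outweigh the
sub-voxel accuracy a weighted scheme would add. Absolute cm³ output is
available behind a flag. If dose and structure grids differ, the dose is
trilinearly resampled onto the structure grid (never the reverse, to
preserve mask topology). Cumulative DVHs use 0.1 Gy bins by default and
always extend one bin past the maximum dose so the curve reaches 0%.

## Risk modelling

* **Logistic fits** are maximum likelihood by IRLS; convergence is declared
  when every score-equation component |X'(y − p)| falls below tol·n
  (tol 1e-8). Standard errors come from the inverse observed information.
  Perfect or quasi-separation is detected when a standardized coefficient
  magnitude exceeds 15 and is reported as an error naming the covariate;
  the linear predictor is clipped at ±30 for numerical stability.
* **Stepwise** starts from the full candidate model and applies the single
  add or drop that most reduces AIC (−2·loglik + 2k) until no move
  improves, so the result is a local optimum over one-variable moves.
* **Best subset** fits all 2^p sub-models (p ≤ 20), including the empty
  model; ties within 1e-9 break toward fewer variables, then earlier
  candidate order. Non-convergent subsets are skipped with a logged
  warning, never silently chosen.
* **Lasso** minimizes (1/n)·negative log-likelihood + λ‖β‖₁ on
  standardized covariates (population SD), intercept unpenalized. The
  solver is penalized IRLS with cyclic coordinate descent on the weighted
  Gram system (the hot loop is numba-compiled); points are iterated until
  the stationarity (KKT) residual falls below 1e-9. The path starts at the
  analytic λ_max = max_j |x_jᵀ(y − ȳ)|/n — where all coefficients are
  exactly zero — and descends a 100-point log grid to 1e-4·λ_max (1e-2
  when p ≥ n), warm-starting each point. The path is truncated early when
  a point fails the stationarity tolerance or the fit approaches
  saturation (> 99% of null deviance explained): the near-MLE end of the
  path is quasi-separated on small cohorts and statistically meaningless.
  λ is chosen by 10-fold stratified cross-validated binomial deviance with
  a fixed seed; reported coefficients are back-transformed to the percent
  scale.
* **Ensemble importance** grows bagged CART trees (Gini splitting, √p
  features per split, bootstrap resampling) and reports both mean decrease
  in out-of-bag accuracy under per-feature permutation and mean total Gini
  decrease. It ranks covariates; it does not produce a formula.
* The published "Risk =" formulas are stored as linear predictors on the
  logit scale — they come from binomial GLM fits, so event probability is
  the sigmoid of the printed right-hand side. Covariates enter in percent
  units (0–100).

## Evaluation

* **AUC** is the Mann–Whitney concordance (ties count ½), identical to the
  trapezoidal area under the empirical ROC. The confidence interval uses
  the DeLong placement-value variance with a normal approximation,
  truncated to [0, 1]; a degenerate variance (AUC at a boundary) yields a
  point interval with a warning. The choice is consistent with the
  symmetric interval reported for the reference cohort.
* **Calibration** follows the optimism-bootstrap convention: the apparent
  curve is a lowess (frac 2/3, no robustifying iterations) of outcome
  against predicted probability on a fixed 50-point grid; each bootstrap
  replicate contributes (curve on the resample) − (resample-model curve on
  the original data), and the bias-corrected curve subtracts the mean
  optimism. When predictions take at most 10 distinct values (grouped
  data) the exact per-group frequencies replace the lowess so a saturated
  model calibrates exactly. Resamples with a single outcome class or a
  separated refit are redrawn and logged. The reported slope/intercept are
  the logistic-recalibration diagnostics, optimism-corrected when
  bootstrapping (the corrected slope reduces to the mean slope of
  bootstrap models tested on the original data, since each replicate's
  training slope is identically 1).
* **Nomogram** point scales are points_j(x) = 100·(β_j·x − min over the
  range of β_j·x)/D with D = max_k |β_k|·range_k, so the most influential
  covariate spans exactly 0–100 points, all scales are non-negative, and
  the total-points axis maps back to probability through the linear
  predictor. Which covariate tops the scale depends on the observed
  covariate ranges, not only on |β|: with equal 0–100 ranges V25 dominates
  the published model, while on simulated cohorts with realistic
  (narrower, level-dependent) ranges V30 typically does.
* **Categorical comparisons** use the Pearson chi-square test of
  independence without continuity correction — the convention validated by
  reproducing the reference cohort's printed p-values (0.707 for machine
  type, 0.929 for fractionation class) exactly from its printed counts.
  The reference cohort's sex and tumour-location p-values are not
  reproducible from printed information under standard tests and are not
  asserted.

## Problem sizes used by the test and acceptance suites

Closed-form and exact-equality checks run on 32³ phantoms and instances
with n ≤ 30. Statistical checks use: n = 2000 for coefficient recovery
(within 3 SE), n = 200 with all 4096 subsets for the best-subset
cross-verification against an independent GLM implementation, 1000
binormal replicates at 200 + 200 for DeLong coverage, and n = 500 with 300
bootstrap replicates for the well-specified calibration-slope check. These
sizes give the statistical power the assertions need while keeping the
full suite around a minute of compute.

## Known limitations

* Demons registration is intensity-based and mono-modal; it has no
  diffeomorphic guarantee, and folding (J ≤ 0) can occur for aggressive
  motion — flagged, not repaired.
* The Jacobian threshold 1.2 is applied to raw J; if a cohort's fields
  come from a registration with a global volume bias, a normalized
  threshold would be more appropriate.
* Voxel-counting DVHs quantize at the voxel scale; Vx values on coarse
  grids carry O(voxel/gradient-length) error, which the
  resolution-doubling test bounds at the default grid.
* The random-forest stage is a ranking tool only; its importances carry
  Monte-Carlo noise at small n even with fixed seeds.
* The cohort simulator's covariate distribution is a stated choice, not an
  estimate of any real population; conclusions about selector behaviour on
  real cohorts should be drawn qualitatively, not numerically.
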