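# Methods

This note documents the models, estimators and design choices behind
`tbtprog`, in the order the pipeline runs them.

## Problem setting

Knee-osteoarthritis (KOA) progression is defined on the OARSI medial
joint-space-narrowing grade (mJSN, ordinal 0–3): a knee whose mJSN
increases between baseline and a fixed follow-up horizon (48 or 60
months) is a *case* (progressor), a knee with constant mJSN a *control*.
A decrease is undefined under this scheme and such knees are excluded
with a logged reason rather than silently relabeled. Eligible knees have
preexisting OA with baseline Kellgren–Lawrence (KL) grade 2 or 3,
complete covariates, and no metallic material in the subchondral zone;
the quality-controlled (QC) analysis additionally drops radiographs with
exposure problems, so the QC subset is by construction contained in the
nonQC subset.

The predictors combine clinical covariates (age, gender, BMI — `cov`;
plus race, WOMAC pain and injury history — `covPlus`), radiological
grades (KL, lJSN, mJSN), a continuous severity score `KLprob`, and 64
trabecular bone texture (TBT) descriptors per knee.

## ROI geometry

A 148-point BoneFinder-style contour outlines the tibia and femur. Two
contour points mark the outer tibial margins (left knee: indices 48
lateral / 64 medial; right knee: 122 / 138 — the lateral/medial roles of
the right-knee pair are a package convention, since only the
medial→lateral ordering matters downstream). The line through these two
points is the *subchondral baseline*; their distance times the pixel
spacing is the knee width.

Sixteen equal square ROIs tile the trabecular area below the baseline in
an 8×2 grid (configurable layout). The ROI side is
`side_mm = width_mm × side_ratio` with `side_ratio = 0.125` by default,
which makes the 8-column patchwork span the knee width exactly and
reproduces a ~10 mm side for typical 80 mm knees. The first ROI row sits
`offset_ratio × side` (default 0.5) below the baseline to stay clear of
the cortical plates. ROI columns are always ordered along the
medial→lateral direction of the baseline, so descriptor column *i* means
the same anatomical position for left and right knees; this replaces an
explicit mirroring resampling pass and keeps a right knee's pixels
untouched.

Pixel conventions: 0-based x = column / y = row, origin top-left, pixel
centers at integers, all physical lengths in mm via the isotropic pixel
spacing (0.1–0.2 mm per pixel). The ROI side is rounded to a whole pixel
count and ROI centers are spaced by that integer, so each ROI's sampling
grid advances in unit-pixel steps; `side_mm` bookkeeping keeps the exact
proportional value. Pixels are sampled on the (possibly rotated) ROI
grid by bilinear interpolation, which preserves constants and is exact
when the grid is integer-aligned.

Exposure QC is operationalized as the fraction of pixels at ≥ 99% of the
saturation level exceeding a threshold (default 0.05). Material
artifacts are metadata-driven (a flag on the record), because in
practice such knees are excluded by reading, not detected
algorithmically.

## Fractal texture descriptors

For each ROI and direction (horizontal/vertical) the empirical variogram

    V(d) = mean over in-block pairs of (I(p + d·e) − I(p))²

is computed at integer pixel lags (plain quadratic variations;
second-order increments are available as a config option). For a
fractional Brownian surface with Hurst exponent H ∈ (0,1),
V(d) ∝ d^{2H}, so ordinary least squares of log₂V on log₂d estimates
H = slope/2, clipped to [0, 1.5] with a flag; the fractal dimension is
FD = fd_offset − H with the surface convention fd_offset = 3
(configurable — only H is convention-free).

Two disjoint scale bands are fitted, as open intervals of lag in mm:

* **micro band (μFD)**: 0 < d < 0.4 mm — at 0.1 mm spacing lags {1,2,3};
* **milli band (mFD)**: 0.6 mm < d < min(2.5 mm, side/4) — the cap keeps
  dozens of pixel pairs per retained lag.

The strict bounds make the micro band hold a single lag at 0.2 mm
spacing; by contract that descriptor is then *invalid* (explicit flag,
never silently filled), and the affected knee still serves every model
that does not use texture. Log base 2 is fixed for reproducibility; the
base is irrelevant to the slope. A zero variogram value inside a band
(flat texture) is a degenerate-texture error for that slot.

16 ROIs × 2 directions × 2 bands give the 64-descriptor vector
(`roi01_h_micro_fd` … `roi16_v_milli_fd`, a stable naming contract).
Estimated H is exactly invariant to affine intensity maps a·I + b
(a > 0), since V scales by a² and only the fit intercept moves.

## Synthetic data

The generator provides every input with known ground truth; nothing in
the pipeline depends on restricted cohort data.

**Texture.** Fractional Brownian surfaces are synthesised spectrally:
white Gaussian noise shaped in the Fourier domain and inverted. Two
discretization effects are handled explicitly. First, a *sampled* fBm is
not band-limited — its grid spectrum is the continuous f^−(2H+2)
spectrum folded over all aliases; the shaping amplitude therefore sums
|f + k|^−(2H+2) over integer offsets |k| ≤ 6. Without this fold the
small-lag variogram slope is biased toward smoothness by up to +0.24 in
H at H = 0.2. Second, the FFT field is periodic, so synthesis runs on a
2× grid and crops. The test-suite cross-checks the generator against an
*exact* independent construction (Cholesky factorization of the fBm
covariance), which has variogram exactly ∝ d^{2H} at every integer lag.

**Landmarks and images.** A stylized tibia/femur contour is scaled by
the knee width; only the point count and extremity indices are
contractual. The extremities sit at half-integer pixel coordinates so
that even pixel widths give patchwork grids aligned to pixel centers,
making the planted-texture round trip exact up to 16-bit quantization.
Artifacts are constructed: overexposure saturates a configurable pixel
fraction at the dtype maximum; material inserts a max-intensity blob
inside the subchondral zone.

**Cohorts.** Each knee carries covariates (age ~ N(62, 9²) yr,
BMI ~ N(30, 5²) kg/m², gender ~ Bernoulli(½), race W/B/O at
0.80/0.15/0.05, WOMAC pain, injury history), KL ∈ {2, 3}, baseline JSN
grades, modality (CR/RG mix 0.7 by default), QC flags (exposure 0.08,
material 0.02), and 16 latent per-ROI Hurst exponents
H ~ N(0.65, 0.05²). Progression is Bernoulli with

    logit P = β₀ + β_age·z_age + β_gender·(g−½) + β_bmi·z_bmi
              + Σ β_tbt[slot]·z_FD(slot) + β_klprob·z_KL

on standardized scales; the linear predictor is stored per knee
(`true_eta`) for oracle scoring. Progressors' medial-ROI Hurst values
are additionally lowered by `hurst_case_shift` (default 0.03), mimicking
the coarsened subchondral texture of progressing knees. Descriptors are
3 − H plus measurement noise (sd 0.04 FD); KL-probability vectors are
Dirichlet perturbations of the one-hot truth (concentration set by
`klprob_noise`, keeping vectors on the simplex); mJSN follow-up is a
single-step increment — decreases are never generated. Defaults give a
realistic ~15–18% progression fraction.

Named regimes fix study conditions for specific checks:

* `null()` — every β zero (chance-level data);
* `noise_free()` — no descriptor noise, exact one-hot KL probabilities,
  no Hurst shift: the recorded table *is* the generative design. Used
  wherever an estimate is compared against generator coefficients,
  because measurement noise attenuates logistic coefficients
  (errors-in-variables) and would make "recovery of the generative β"
  ill-defined;
* `recovery()` — noise-free with effects sized so that a ±10% band
  exceeds the maximum-likelihood sampling error at n ≈ 5000 (the binary
  gender covariate has coefficient SE ≈ 0.08 at that n, so only |β|
  well above it is identifiable to 10%);
* `oracle_auc_075()` — noise-free with betas calibrated once (against
  the analytic score at n = 4×10⁵) so the Bayes AUC is ≈ 0.75, frozen.

What passing tests on these cohorts do **not** show: robustness to
reading variability in KL/JSN grades, femoral texture, non-logistic
outcome mechanisms, informative missingness, or subject-level
correlation between the two knees of one person (knees are treated as
units, as in the modeled protocol; a subject-grouped CV profile exists
but is off by default).

## KLprob

`KLprob = Σ_k w_k p_k` over the five KL-grade probabilities; default
weights (0, 1, 2, 3, 4) give the expected grade, a continuous severity
score. One-hot input reproduces the integer grade; off-simplex input
(|Σp − 1| > 10⁻⁶) is rejected.

## Models and evaluation

Nine logistic models: M1 cov; M2 cov+TBT; M3 cov+mJSN+lJSN; M4 cov+KL;
M5 cov+KLprob; M6 cov+lJSN+mJSN+TBT; M7 cov+KLprob+TBT; M8
cov+KLprob+lJSN+TBT; M9 covPlus+KLprob+lJSN+TBT. M8 deliberately omits
baseline mJSN (collinear with KLprob and entangled with the outcome
definition). Gender and injury are 0/1; race is one-hot against the W
reference; JSN grades enter as numeric ordinals (factor encoding
available in config).

Fitting is maximum likelihood via Newton/IRLS (statsmodels backend):
predictors standardized internally, coefficients mapped back to the
original scale, convergence at max |Δβ| < 10⁻⁸ or 100 iterations;
complete separation yields a flagged result with a warning. Each model
uses the rows complete for its own predictors (complete-case per
model). AIC = 2k − 2·loglik.

**Backward AIC selection** over the 64 descriptors (clinical predictors
forced, never removable): at each step the single candidate whose
removal gives the lowest AIC is dropped iff that AIC improves; ties
resolve by descriptor name order for determinism; no re-entry. The
accepted-drop AIC trace is strictly decreasing. Selection runs once on
the full training table before cross-validation (as in the modeled
protocol); a nested per-fold variant is available as the leakage-safe
option.

**Repeated CV**: stratified k-fold (default k = 10) repeated R times
(default 300; scaled to ~20 in tests and analyses, where the repeat
mean is already stable); per repeat the out-of-fold predicted
probabilities are pooled into one AUC; reported AUC is the repeat mean
with a 2.5/97.5-percentile interval. Stratification is used because
small case counts make unstratified folds degenerate. ACC and the
diagnostic odds ratio DOR = (TP·TN)/(FP·FN) are computed at a score
threshold chosen by Youden's J on the scoring set (fixed-0.5 rule
available); zero cells get the Haldane 0.5 correction so a perfect
classifier reports a finite DOR.

**AUC** is the mid-rank Mann–Whitney statistic (ties count ½), exactly
invariant to strictly increasing score transforms. **DeLong**
structural-components covariance gives the variance of a paired AUC
difference and a two-sided normal test; identical score vectors give
p = 1 exactly, and the statistic is antisymmetric in the model order.
Pairwise p-values are reported raw (optional Holm adjustment); the
test-suite checks the asymptotic p against a 10⁴-draw score-swap
permutation null.

**Cross-cohort transfer**: descriptor selection, standardization
constants, coefficients and the accuracy threshold are all frozen on
the training cohort; the test cohort is only scored. The test AUC gets
a DeLong confidence interval. With train = test the protocol degenerates
to resubstitution, which is the identity check in the tests.

## Numerical and testing choices

* Variogram code is vectorized; equality with a brute-force double loop
  is asserted to 10⁻¹⁰ on 64² blocks.
* Per-repeat CV fold seeds derive from one `SeedSequence`, so every
  protocol is bit-reproducible under a fixed seed.
* The rotation-equivariance check renders the scene with band-limited
  texture (no alias folding) at the generator's default roughness
  H = 0.65 and rotates it with cubic interpolation: a fully aliased
  fractal has no interpolation-stable lag-1 statistic (any resampling
  moves micro-band FD by ~0.2 at H = 0.5), whereas a radiograph behind
  a detector PSF does. Translation invariance is exact and asserted at
  10⁻⁶ relative on all 64 descriptors.
* Degenerate inputs fail loudly and specifically: coincident extremity
  landmarks, wrong-laterality index pairs, out-of-bounds ROIs,
  single-lag bands, zero variograms, off-simplex probability vectors,
  one-class outcomes.

## Problem sizes in the analyses

The numbered analysis scripts use two cohorts of 2000 and 800 knees
(horizons 48 and 60 months), a 12-knee imaging subset for the rendering
round-trip, 20 CV repeats and n = 1500 per arm for transfer checks —
sizes at which every reported quantity's Monte-Carlo error is small
compared to the effects discussed, while the full battery runs in
minutes on one CPU.

## Known limitations

* The landmark template is stylized; real BoneFinder contours vary in
  shape. Only the count and extremity conventions are contractual.
* The micro band holds three lags at 0.1 mm spacing — enough for a
  slope, but FD estimates at that scale lean on few points; the
  optional resampling of 0.2 mm images to 0.1 mm is off by default
  because it manufactures information.
* Milli-band H estimates carry a small negative finite-window bias at
  high H (≈ −0.08 at H = 0.8), a known property of large-lag variogram
  estimation on finite blocks.
* Subject-level clustering (two knees per person) is not modeled.
* Whether the upstream variogram protocol used first- or second-order
  increments, and its exact lag set, is configurable rather than
  asserted; defaults are first-order with all integer lags in band.
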