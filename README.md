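# tbtprog

Trabecular bone texture descriptors and progression models for knee
osteoarthritis (KOA) radiographs.

Structural progression of KOA — an increase in the OARSI medial
joint-space-narrowing grade (ΔmJSN > 0) over 4–6 years — is hard to
predict from clinical covariates alone. The subchondral trabecular bone
remodels early in the disease, and its radiographic texture carries
prognostic signal. This package implements that analysis end to end for
researchers working with knee radiograph cohorts:

* **ROI geometry** — from a 148-point bone contour, fit the tibial
  subchondral baseline through the outer tibial margins, measure the
  knee width, and place a patchwork of 16 equal square ROIs (side
  = 0.125 × knee width) over the tibial trabecular area;
* **fractal texture** — per ROI, directional empirical variograms
  V(d) = E[(I(p+d·e) − I(p))²]; since V(d) ∝ d^2H for a fractal
  surface with Hurst exponent H, the log–log slope fitted on two scale
  bands (micro: d < 0.4 mm; milli: 0.6 mm < d < min(2.5 mm, side/4))
  gives the
  fractal dimensions μFD and mFD = 3 − H per direction — 64 descriptors
  per knee;
* **cohort pipeline** — eligibility (2 ≤ KL < 4, no material artifacts;
  QC variant also drops exposure problems), case/control labeling from
  ΔmJSN, the continuous severity score KLprob = Σ_k k·p_k from a
  classifier's five KL-grade probabilities, and backward AIC selection
  over the 64 descriptors;
* **model evaluation** — nine logistic models (clinical covariates,
  JSN grades, KL, KLprob, TBT and combinations), stratified 10-fold
  cross-validation repeated up to 300 times, AUC/ACC/diagnostic-odds-
  ratio summaries, DeLong tests for correlated ROC curves, and a
  cross-cohort protocol that freezes everything on one cohort and
  scores the other;
* **synthetic data** — fractional-Brownian trabecular textures with
  known Hurst exponent rendered under a synthetic tibial plateau,
  landmark sets, and cohorts whose progression follows a logistic model
  with known coefficients, so the whole chain is testable without any
  restricted cohort access.

## Worked example

```python
from tbtprog import (generate_landmarks, generate_fbm_field,
                     synthesize_knee_image, fit_subchondral_baseline,
                     build_patchwork, compute_tbt_descriptors)

lm = generate_landmarks(knee_width_mm=80.0, laterality="left", seed=7)
baseline = fit_subchondral_baseline(lm)
pw = build_patchwork(baseline, lm.pixel_spacing)
fields = [generate_fbm_field(pw.side_px, hurst=0.5, seed=300 + i)
          for i in range(16)]
img = synthesize_knee_image(lm, fields)
desc = compute_tbt_descriptors(img, pw)
print(baseline.width_mm, pw.side_mm, pw.side_px)
print(desc.n_valid, desc.to_series().filter(like="micro").mean())
```

prints

```
80.0 10.0 100
64 2.4948431252033005
```

— an 80 mm knee gives 10 mm (100 px) ROIs; all 64 descriptor slots are
valid; and the mean micro-band fractal dimension over the 16 planted
H = 0.5 textures is ≈ 2.5, i.e. 3 − H, which is the estimator working.

The same flow is available from the shell:

```bash
tbtprog simulate --out cohort/ --n 50 --seed 1 --images
tbtprog extract  --data cohort/ --out cohort/features.csv
tbtprog evaluate --features cohort/features.csv --out results/ --repeats 20
tbtprog cross-cohort --train a/features.csv --test b/features.csv --out cross.csv
```

## Analysis scripts

`analysis/` holds the numbered drivers of the full study on synthetic
cohorts: `01_simulate_cohorts.py` (two cohorts, 2000 and 800 knees,
48/60-month horizons, written under `scratch/`),
`02_extract_descriptors.py` (imaging round trip: rendered radiographs →
extracted FD vs planted texture), `03_evaluate_models.py` (descriptor
selection and the nine-model battery under repeated CV; with the default
synthetic effect sizes the texture models reach AUC ≈ 0.91 against
≈ 0.58 for covariates alone) and `04_cross_cohort.py` (Model 8 frozen on
one cohort and scored on the other, both directions). Summary tables
land in `results/`.

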