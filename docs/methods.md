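# Methods

## Problem and model

A lesion-detection network applied to a chest radiograph yields a 2D
class-activation probability map: per-pixel values in [0, 1] expressing
how likely each pixel belongs to a pulmonary nodule or mass.  `camvol`
estimates the nodule's 3D volume from two scalars derived from that map —
the area A (mm²) of the region of interest above a 0.2 probability
cutoff, and the mean probability P over that region — and classifies the
interval change of volume between serial radiographs.

The predictor family is polynomial regression on (A, P) at three degrees:

* **degree 1** — affine: `V = b0 + b1 A + b2 P`;
* **degree 2** — full quadratic in (A, P);
* **degree 1.5** (the *unit-adjusted* model) — the complete cubic in
  (√A, √P), ten monomials `A^(i/2) P^(j/2)` with `i + j ≤ 3`.  The
  half-power ladder is motivated dimensionally: for a projected sphere
  V ∝ A^{3/2}, so a basis reaching A^1.5 converts an mm² feature toward
  an mm³ response.

Each degree has a univariable (area-only) and multivariable (area +
probability) variant; all six are fit by ordinary least squares and
compared by training RMSE.  Two published fitted models ship as frozen
constants: the degree-1 plane and the ten-term degree-1.5 multivariable
equation.  The ten printed coefficients, placed on the basis above in
ascending half-degree order, reproduce the published serial worked
example (area 761.6 → 1079.6 mm², mean probability 0.514 → 0.529 maps to
8.50 → 16.35 cm³ within 0.005 cm³), which validates both the basis
reconstruction and the coefficient transcription.

The univariable degree-1.5 basis uses the full ladder {1, √A, A, A^1.5}
rather than {1, A^1.5} alone, mirroring the complete multivariable basis;
this is a design choice where the published description is silent.

## ROI extraction

The map is thresholded at p > 0.2 (strict, so a uniform-cutoff map has no
ROI); connected components use 8-connectivity.  Components are ordered by
descending area (ties: descending maximum probability, then row-major
centroid) and truncated to three per image, matching how nodules were
enumerated.  Per ROI five descriptors are computed: pixel count × spacing²
(area), the probability-weighted area WOAP = Σ p × spacing² (which equals
the area when p ≡ 1 inside the region), and the mean / median / maximum
probability.  Image-level positivity is max pixel probability ≥ 0.15, the
maximum standing in for the network's image-level score.  Pixel spacing
must be isotropic; anisotropic input is rejected rather than averaged.

Only area and mean probability feed the regression models; WOAP, median
and maximum are computed and reported but not modelled.

## Synthetic cohort generator

No public imaging accompanies the analysis, so a generator reproduces the
cohort's statistical structure and renders matching probability maps.
What it emulates, with defaults:

* **Composition** — 147 images of 72 patients, 104/25/18 images carrying
  1/2/3 nodules (208 nodule observations).  Every patient keeps the same
  nodule multiplicity across ≥ 2 serial timepoints; a deterministic
  partition assigns patients and timepoint counts so the image totals
  match exactly.
* **Volumes** — lognormal truncated to [110, 70 400] mm³ with (μ, σ)
  solved numerically so the *truncated* distribution has mean 9 370 and
  SD 11 690 mm³ (the published moments describe range-limited
  observations; the closed-form parent match `σ² = ln(1+(SD/mean)²)`
  initialises the solver but would give a truncated mean of only
  ≈ 8 900 mm³).  Draws use inverse-CDF sampling for determinism.
* **Serial change** — follow-up volume = baseline × factor; growth
  factors U[1.3, 2.5] with probability 0.5, shrinkage U[0.4, 0.77]
  otherwise.  Note that with the ±25 % no-change band, shrink factors in
  (0.75, 0.77] are labelled "no change" in truth — the band is a
  reporting threshold, the factors are the biology.
* **Forward model** — projected radius `r = (3V/4π)^{1/3}`; observed
  contour radius `r·exp(η/2)` with `η = λ·c + σ_A·e₁`, giving CAM area
  `π r² e^η`; peak probability `0.2 + 0.8·logistic(1.2·t + 0.8)` with
  latent `t = 0.25·z_V + λ·c + σ_P·e₂` (z_V standardized log-volume);
  region-mean probability from the Gaussian blob profile in closed form,
  `(peak − 0.2)/ln(peak/0.2)`.  Here `c ~ N(0,1)` is a per-nodule
  *conspicuity* factor shared between area and probability and persistent
  across timepoints, while `e₁, e₂` are per-observation noise.  The
  shared factor is essential: probability must correlate strongly with
  area (≈ 0.73) yet weakly with volume (≈ 0.22), which no model with
  independent area and probability noise can produce (it forces
  ρ(A,P) ≈ ρ(P,V)/ρ(A,V) ≈ 0.38).
* **Calibration** — the three noise scales (σ_A = `area_noise_sd`,
  σ_P = `prob_noise_sd`, λ = `prob_vol_decoupling`) were tuned once by a
  finite-difference Newton step on the mean Spearman correlations of
  default cohorts over 200 seeds, targeting (0.58, 0.73, 0.22), and
  frozen at (0.635, 0.369, 0.992).  Across seeds the cohort-level
  correlations then scatter with SD ≈ (0.06, 0.04, 0.08) around
  (0.580, 0.731, 0.219).
* **Rendering** — each nodule is a radial Gaussian blob with the stated
  peak, scaled so its 0.2 iso-contour radius equals the noisy contour
  radius; blobs combine by maximum on a zero background, values clipped
  to [0, 1].  Centers are rejection-sampled with pairwise separation
  2× the sum of contour radii, relaxed stepwise to 1× (still
  non-merging) when the grid cannot host the stricter spacing.  Contour
  radii are capped at 20 % of the shorter grid edge: the emulated
  detector is trained on lesions of bounded size and an uncapped
  lognormal tail would occasionally exceed the radiograph.  An optional
  per-image multiplicative probability bias (`manufacturer_bias_sd`, off
  by default) emulates cross-manufacturer intensity inconsistency.

What the generator does **not** emulate: radiographic anatomy (ribs,
mediastinum, overlapping structures), detector false positives and missed
nodules, irregular lesion shape, and reader behaviour.  Passing tests
therefore demonstrate the pipeline's statistical and numerical
correctness under the published cohort's correlation structure, not
clinical performance on real radiographs.

## Numerical choices

* OLS is solved by SVD (`numpy.linalg.lstsq`) after scaling each design
  column to unit maximum absolute value — columns span ~10 orders of
  magnitude (A^1.5 vs P^1.5) — and coefficients are rescaled back; the
  result is the exact least-squares solution.  Rank deficiency after
  scaling raises an error naming the dependent columns.  No
  regularisation, no intercept suppression.
* Predictions are not clamped by default (`clamp_zero` floors them at 0);
  serial assessment floors predictions at 1 mm³ so change ratios stay
  defined under degenerate extrapolation.
* RMSE is training RMSE (no held-out split), matching how the model
  family is compared in the source analysis; there is no internal
  validation.
* Spearman correlations use average ranks for ties; constant input is an
  error, not NaN.
* Probability maps are quantised to 16-bit PNG (resolution 1/65535, far
  below any modelled effect); tables are CSV at 1e-6 precision; model
  JSON round-trips coefficients bit-exactly.
* All randomness flows from one integer seed through
  `numpy.random.Generator`; no global state.  Fixed seed ⇒ byte-identical
  tables.

## Serial change

Consecutive-timepoint observations of a nodule are paired; relative
change `v₁/v₀ − 1` beyond ±25 % (a configurable band consistent with
accepted CT-volumetry repeatability limits) is classified increased /
decreased, otherwise no change.  The same rule applied to true volumes
gives the truth class, so the predicted-vs-truth concordance isolates
prediction error.  Because the band is additive in relative change it is
not ratio-symmetric: a ratio in (1.25, 4/3) is "increased" forward but
"no change" when the pair is reversed.

On the frozen default cohort, in-sample predictions of the degree-1.5
multivariable model agree with the truth class for 0.538 of the 106
serial pairs (chance ≈ 1/3 under the generator's class mix).  This
moderate figure is a direct consequence of calibration: an area–volume
rank correlation of 0.58 implies parameter noise comparable to the
bounded change factors, capping achievable interval-change concordance.

## Problem sizes

Default analyses run on the 147-image / 208-observation cohort; the
distribution-calibration check uses 10⁴–10⁵ volume draws; the
acceptance script averages the cohort correlations over 32 replicate
cohorts (6 656 observations) to report stable estimates of the calibrated
population values.

## Known limitations

* The generator's correlations are Gaussian-copula-like by construction;
  real CAM parameters may have heavier tails and nonlinear dependence.
* The degree-1.5 univariable ladder choice and the WOAP definition are
  reasoned reconstructions where the published description is incomplete.
* RMSE values on synthetic cohorts are not comparable to the published
  clinical RMSEs (7 975.6 / 9 449.9 mm³), which depend on an unreleased
  dataset; only the model *ordering* transfers, and it is what the tests
  assert.
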