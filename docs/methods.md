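# Methods

This note documents the models, conventions, numerical choices and
limitations behind `lordquant`. It is organised along the pipeline:
coordinate conventions, registration, atrophy mapping, scalar metrics,
longitudinal statistics, and the synthetic cohort generator.

## Coordinate conventions

Pixel coordinates are 0-based with pixel-centre semantics, `x`
increasing rightward (columns) and `y` downward (rows). All analysis
runs in **right-eye format**: left eyes are mirrored about the vertical
image midline (image, masks, fovea and optic-nerve-head (ONH)
coordinates all transformed, original laterality recorded), after which
the ONH lies nasal of the fovea, i.e. at larger `x`. The mirror axis is
the image midline rather than the fovea; no re-centering is needed
because all downstream geometry is fovea-relative. Mirroring is an
involution on coordinates and preserves mask pixel counts.

## Registration

Follow-up exams are aligned to their baseline from ≥ 9 manually (or
synthetically) identified corresponding points. The homography is
estimated with the conditioning-normalised direct linear transform
(centroid shift + scale normalisation before solving; scikit-image's
`ProjectiveTransform`), which is exact for noise-free points and
least-squares under jitter; fewer than `min_points` (default 9) pairs,
duplicates or collinear configurations are rejected. Warping is
inverse-mapped: masks nearest-neighbour (stay binary), images bilinear,
out-of-frame pixels background. Root-mean-square reprojection error is
exposed as quality control for the manual step.

Segmentation/registration order: the pipeline segments (or receives
masks) in the follow-up frame and warps the masks to baseline. Whether
masks should instead be drawn on already-registered images is a real
design fork; both orders are supported because `register_exam` warps
image and masks identically, and the synthetic path exercises the
warp-the-masks order. Registration happens in the eye's native frame —
control points are picked on the native images — and flipping to
right-eye format follows.

## Superpixel atrophy mapping

Eyes differ in fovea–disc distance, vertical disc offset and pixel
scale. Normalisation is two-step:

1. **Shear.** `s = (y_onh − y_fovea)/(x_onh − x_fovea)`; pixels with
   `x ≥ x_fovea` (fovea column inclusive — the boundary choice affects
   one pixel column) are mapped `y′ = y − s·(x − x_fovea)`; the
   temporal half and all horizontal coordinates are untouched. After
   the shear, fovea and ONH share a horizontal axis (± 0.5 px).
   Resampling is nearest-neighbour on the inverse map, preserving mask
   binarity; columns shifted by integer amounts keep their pixel counts
   exactly.
2. **Grid.** The superpixel size is `n = round(d/20)` pixels (half away
   from zero) where `d` is the sheared fovea–ONH horizontal distance,
   so 20 superpixels separate fovea and disc. Superpixel (0, 0) is
   *centred* on the fovea (a centre vs corner anchoring had to be
   fixed; centre matches how the landmark maps read most naturally);
   grid index of a pixel is `floor((x − x_fovea)/n + 1/2)`.

With an integer `n`, the ONH centre lands in column 20 exactly when the
rounding residual `|d − 20n| ≤ 10 px` stays below `n/2` — guaranteed
whenever `n ≥ 20 px`, i.e. `d ≥ 390 px`. The synthetic anatomy defaults
(below) respect this bound, so "fovea = (0,0), ONH = (20,0)" is an
assertable invariant on every generated eye. Distances under 20 px are
rejected as unresolvable.

Each superpixel scores `p` = atrophic fraction of its in-frame pixels,
peripapillary pixels excluded from the numerator; clipped edge
superpixels are scored over available pixels rather than padded. A
superpixel is atrophic when `p ≥ θ` with θ = 0.5 (inclusive).
Conservation holds by construction: `Σ p·(pixel count)` equals the
excluded-adjusted atrophic pixel count.

**Age-stratified prevalence.** Binarized maps are pooled on the common
grid frame and stratified by age at exam into `(−∞,55], (55,60],
(60,65], (65,70], (70,∞)` years (upper-inclusive half-open — the
stratum labels had overlapping endpoints and a convention had to be
fixed). Per location, prevalence = 100·(atrophic exams)/(exams
observing that location); locations with fewer than 4 exams are
censored. Multiple exams per eye may fall in one stratum (no
per-patient weighting by default; frequently imaged patients are
over-represented, a known limitation), and narrow-field exams simply
contribute no observation at peripheral locations.

## Scalar metrics

- **Area of atrophy.** `AA = (atrophy pixels inside the circle, minus
  peripapillary pixels) · scale²/10⁶` mm², circle membership by
  pixel-centre distance, measured in the registered but *unsheared*
  frame (the shear exists only for the spatial map). Circles: 6 mm
  (central ETDRS) and 14 mm (largest inside a 55° field), both
  fovea-centred; a circle extending past the raster is computed on the
  available field and flagged. √AA is carried as the analysis scale.
- **EZ width.** On each side of the fovea, the distance to the first
  ellipsoid-zone absence run of lateral extent ≥ `min_break_extent`
  (default 2 a-scan spacings — operationalising "clear EZ loss" vs mere
  signal attenuation, configurable). Total = temporal + nasal, exactly.
  A side with no qualifying break is censored at the scan edge and
  flagged rather than dropped or imputed; an absent EZ at the fovea
  yields (0, 0, 0).
- **Foveal thicknesses.** Strictly vertical distances at lateral 0:
  CRT from ILM to the posterior RPE–Bruch's boundary, PR+RPE from the
  ELM to the same boundary. Missing boundaries return NaN, never a
  silent zero.
- **BCVA.** Numeric LogMAR passes through; CF/HM/LP/NLP map to
  2.6/2.7/2.8/2.9 LogMAR and are flagged end-stage; end-stage rows are
  excluded from progression fits but kept for descriptive tables.

## Longitudinal statistics

- **Mixed model.** `value ~ age` with a patient random intercept and an
  eye random intercept *nested* within patient (the natural reading of
  "patient and eye" intercepts for paired-eye designs; statsmodels
  `MixedLM` with a variance component per eye). Estimates by REML;
  slope CI is Wald at the REML standard error; the age effect is a 1-df
  likelihood-ratio test comparing full-ML fits with and without age.
  R² is reported as the marginal (fixed-effects) variance share
  `var(Xβ)/(var(Xβ)+Σ variance components+σ²)`. Eyes with < 2 visits
  are dropped; fewer than 3 distinct ages raises an error.
- **Hinge regression.** Continuous two-segment model fitted on pooled
  data; ψ profiled by grid search (0.1-year default step over the
  interior of the observed age range, i.e. ≥ 2 distinct ages on each
  side), refined by local quadratic interpolation of the RSS profile
  (skipped when the grid minimum is an effectively exact fit, where the
  parabola is numerical noise). The hinge design contains the single
  line (β₀ = β₁), so hinge RSS never exceeds the line RSS. 95% CI by
  case-resampling bootstrap over patients (percentile, 1000 reps
  default, seeded); boundary minima are flagged. The profile solver
  uses closed-form batched normal equations, exploiting that the two
  hinge basis columns are pointwise orthogonal.
- **Repeated-measures correlation.** ANCOVA decomposition (common
  slope, subject intercepts) via pingouin; equal to the Pearson
  correlation of subject-centred series, hence invariant to per-subject
  offsets. Subjects with one complete visit are dropped with a warning.
  The CI is Fisher-z on the error degrees of freedom (the library's own
  interval is rounded to two decimals, too coarse for calibration
  work).
- **Normalised rates.** `100·|slope|/dynamic range` %/year. Default
  ranges: √(π(d/2)²) for √AA of a d-mm circle (12.41 mm at 14 mm,
  5.32 mm at 6 mm); the lateral scan extent for EZ width; the cohort
  baseline median for CRT and PR+RPE; a configurable usable LogMAR span
  (default 1.5) for BCVA.
- **Multiplicity.** Family-wise Bonferroni, `min(1, p·m)`.

## Synthetic cohort generator

The generator defines the study conditions the tests and recovery
experiments run under; its defaults are fixed once and documented here.

**Trajectories.** Every metric follows a hinge:
`value(age) = α + β₀·min(age−ψ,0) + β₁·max(age−ψ,0) + u_patient +
u_eye + ε`. Default (ψ, β₁, α) per metric plant the cohort-level
estimates for this disease: √AA(14 mm) (53.9 y, 0.53 mm/y, 0),
√AA(6 mm) (56.3, 0.24, 0), EZ width (50.8, −257 µm/y, 6000 µm), CRT
(62.3, −4.7 µm/y, 280 µm), PR+RPE (60.0, −3.8 µm/y, 110 µm), BCVA
(70.3, +0.05 LogMAR/y, 0.1). Pre-breakpoint slopes are 0 (metrics flat
until the inflection). **Variance components are free generator
parameters** — the source estimates do not constrain them — chosen at
magnitudes a clinical cohort of this kind plausibly shows (e.g. √AA:
patient 0.5, eye 0.3, residual 0.3 mm; EZ: 300/150/150 µm; CRT:
20/10/8 µm; BCVA: 0.1/0.05/0.05 LogMAR); they are inputs to, not
outputs of, the recovery experiments. Fellow eyes share the patient
intercept and a configurable fraction (default 0.8) of the visit-level
residual; for calibrated interocular-correlation experiments the
per-eye noise SD is set in closed form from
`r = var_w/(var_w + σ_e²)`, `var_w` being the within-patient variance
of the shared trajectory.

**Cohort shape.** Default 16 patients, both eyes, baseline age uniform
in 52–68 y, 2–6 visits spaced 0.8–1.8 y — mimicking a retrospective
natural-history clinic series with a median follow-up around five
years. Explicit per-patient visit ages may be supplied instead.

**Anatomy.** Pixel scale uniform in 10–11 µm/px and fovea–disc distance
4400–4900 µm on a 1024-px raster (high-resolution 55°-class imaging);
vertical disc offset up to ±10% of the distance so the shear has real
work. These bounds keep the fovea–disc distance ≥ ~398 px, which makes
the ONH-at-(20, 0) grid invariant deterministic (see above). Left eyes
are generated mirrored.

**Scalloped atrophy.** Masks are unions of overlapping discs laid down
by a seeded frontier process: the first lobe seeds temporal to the
fovea; each subsequent lobe branches off an earlier disc centre (mostly
a recent one, so growth keeps a frontier) with a nasally biased offset.
A pure unbiased random walk was tried first and abandoned: it drifts
out of the paintable region or stalls on already-painted area and
cannot reliably reach targets near the circle capacity. When lobe
growth stagnates, the mask advances by one boundary ring (pixels added
in a fixed temporal-first order). The disc/ring sequence depends only
on the seed — never on the requested area — so masks for increasing
targets are nested; the final lobe's radius is tuned by bisection to
land the realised pixel area within 0.5% of the target (2% is the
guaranteed contract). Painting is confined to the 14-mm measurement
circle with the peripapillary annulus excluded, so the planted target
equals the peripapillary-excluded area the quantification stage
measures. Because the planted hinge is unbounded while a circle is not,
targets are clipped at 95% of the circle capacity (real atrophy
saturates the same way). A peripapillary annulus at the ONH is added in
30% of eyes to exercise the exclusion rule. FAF intensity rasters are
schematic (noisy mid-grey background, hypo-autofluorescent atrophy,
dark disc) — no photorealistic texture synthesis.

**Misregistration.** Follow-up exams are warped by a mild projective
transform built from random corner displacements (default ≤ 12 px); the
planted homography goes to the ledger and ≥ 9 exact corresponding
points (reprojection error ~ machine precision, non-collinear grid) are
emitted for the registration stage to consume.

**OCT and BCVA.** Foveal-scan derivatives carry a planted EZ extent
split near-symmetrically about the fovea (a-scan spacing 12 µm, ± 3.6 mm
default), occasionally with a single-sample dropout inside the intact
region to exercise the clear-loss rule, plus layer heights reproducing
the planted CRT and PR+RPE exactly. The clinical table writes numeric
LogMAR with occasional counting-fingers codes (default 5% of rows)
standing in for unquantifiable acuity.

**Determinism.** All randomness flows from one seed through
`SeedSequence` substreams keyed by (patient, eye, purpose); identical
configs produce byte-identical tabular outputs.

## What the synthetic data does and does not show

The generator reproduces the *statistical* structure the estimators
assume (hinge mean trajectories, two-level random intercepts, shared
fellow-eye variation, censorable EZ traces, end-stage acuity codes) and
the *geometric* structure the mapping assumes (anatomical variability,
planted homographies, scalloped temporal-to-nasal growth). Passing
recovery tests therefore shows the estimators and geometry are
implemented correctly, not that real FAF segmentation, manual
control-point picking or manual OCT measurement have the error
characteristics assumed here: real masks have grader variability, real
control points have localisation noise, real EZ traces have attenuation
artefacts more complex than single-sample dropouts, and real cohorts
mix 30°- and 55°-class fields. Progression-rate magnitudes recovered
from synthetic cohorts say nothing new about the disease — they are
planted inputs.

## Problem sizes and numerical settings

Recovery experiments use desk-scale cohorts (14–25 patients, both eyes,
5–21 annual visits; 100 replicate cohorts for coverage checks with
500-replicate bootstraps), sizes at which the estimators' CIs are a few
percent wide and the checks are informative. Convergence: REML via
lbfgs with a powell fallback; hinge ridge jitter 1e-10 on the normal
equations to keep degenerate grid points solvable; bootstrap resamples
with fewer than 4 distinct ages are skipped (the fit is undefined
there) and the CI requires at least half the resamples to survive.

## Known limitations

- The hinge model is population-pooled; subject-level breakpoints are
  not modelled (bootstrap-by-patient quantifies, but does not remove,
  the resulting between-patient heterogeneity in ψ̂).
- The eye random effect is modelled as nested within patient; a crossed
  structure for "laterality" as such is not currently exposed.
- Spatial prevalence counts exams, not patients; no weighting
  correction is applied by default.
- The generator does not simulate choroidal neovascularisation, cystoid
  macular edema, epiretinal membranes, reticular pseudodrusen or
  speckled autofluorescence.
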