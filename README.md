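# lordquant

Quantitative natural-history pipeline for **late-onset retinal
degeneration (LORD)**, the autosomal-dominant dystrophy caused by
heterozygous *C1QTNF5* variants. The package is aimed at researchers
modelling disease progression from longitudinal retinal imaging: it
implements anatomically normalised fundus-autofluorescence (FAF)
atrophy mapping, extraction of the scalar outcome metrics used in
natural-history studies (area of atrophy, ellipsoid-zone width, foveal
thicknesses, visual acuity), and the longitudinal statistics that turn
them into progression rates and inflection ages — all exercised against
a fully synthetic cohort generator with known ground truth, since the
clinical records such studies draw on are not publicly shareable.

## What it computes

**Atrophy mapping.** Atrophy is segmented on FAF as definite decreased
autofluorescence (binary masks are inputs). Left eyes are flipped to
right-eye format; follow-up exams are aligned to baseline by a
projective transform estimated from ≥ 9 corresponding control points.
The area of atrophy AA is measured inside fovea-centred circles of 6 mm
(central ETDRS circle) and 14 mm (largest circle in a 55° field),
peripapillary atrophy excluded, and analysed as √AA (mm) so growth-rate
estimates do not depend on baseline lesion size. For spatial analysis,
a vertical shear levels the optic nerve head (ONH) with the fovea and a
per-eye superpixel grid is built with exactly 20 superpixels separating
fovea (index (0, 0)) and ONH (index (20, 0)); each superpixel carries
its atrophic pixel fraction p and is called atrophic when p ≥ 0.5.
Pooled maps give age-stratified prevalence (5-year strata from age 55,
locations with < 4 exams censored).

**Progression statistics.** For each metric *y* with age *a*:

- *Linear mixed model* — `y ~ a` with random intercepts for patient and
  eye-within-patient (REML); the progression rate is the fixed slope β
  with Wald 95% CI, the age effect is tested by a 1-df likelihood-ratio
  test of ML fits.
- *Hinge (piecewise-linear) model* —
  `y = α + β₀·min(a − ψ, 0) + β₁·max(a − ψ, 0)`; the breakpoint ψ (the
  "inflection age" at which the metric starts changing) is profiled on
  a 0.1-year grid and its 95% CI comes from a patient-resampling
  bootstrap.
- *Repeated-measures correlation* — within-subject ANCOVA (common
  slope, subject intercepts) for interocular and inter-metric
  relationships.
- Rates are normalised by each metric's dynamic range
  (100·|β|/range, %/year) and p-values are Bonferroni-corrected.
  Qualitative end-stage acuity codes (CF/HM/LP/NLP → 2.6/2.7/2.8/2.9
  LogMAR) are excluded from progression fits.

**Synthetic cohort.** `lordquant.synthetic_cohort` generates cohorts
with hinge-shaped trajectories (patient/eye random intercepts, shared
fellow-eye latent structure), scalloped atrophy masks growing from the
temporal retina nasally, per-eye anatomical variability, planted
projective misregistration of follow-ups with exact control points, OCT
foveal-scan derivatives, and a clinical BCVA table — all reproducible
from a single seed and accompanied by a ground-truth ledger.

## Worked example

```python
import numpy as np, pandas as pd
import lordquant as lq

# a cohort whose sqrt-AA(14 mm) trajectory has its inflection at 53.9 y
# and grows 0.53 mm/y thereafter
params = lq.HingeParams(breakpoint_age=53.9, pre_slope=0.0, post_slope=0.53,
                        intercept_at_breakpoint=0.0, patient_intercept_sd=0.5,
                        residual_sd=0.3)
rng = np.random.default_rng(1)
rows = []
ages = np.arange(55.0, 76.0)
for p in range(20):
    u = rng.normal(0, params.patient_intercept_sd)
    for eye in ("OD", "OS"):
        vals = lq.simulate_hinge_series(params, ages, rng, u_patient=u)
        rows += [dict(patient_id=f"P{p}", eye=eye, age_years=a, value=v)
                 for a, v in zip(ages, vals)]
df = pd.DataFrame(rows)

fit = lq.fit_lmm(df)
print(f"slope {fit.slope:.3f} mm/y  CI ({fit.slope_ci[0]:.3f}, {fit.slope_ci[1]:.3f})")
print(f"normalized rate {lq.normalized_rate(fit.slope, (3.14159*49)**0.5):.2f} %/y")
```

prints

```
slope 0.531 mm/y  CI (0.528, 0.534)
normalized rate 4.28 %/y
```

i.e. the mixed model recovers the planted 0.53 mm/y growth of √AA, and
dividing by the dynamic range of the 14-mm circle (√(π·7²) ≈ 12.41 mm)
expresses it as ≈ 4.3% of the measurable range per year.

The full imaging pipeline runs from the command line:

```bash
lordquant run --workdir run --seed 3 --n-patients 8
```

which simulates a cohort, flips/registers/maps every exam, quantifies
all metrics and writes `metrics.csv`, `fits.csv`, `prevalence.csv` and
a plain-text report into the work directory.

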