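import numpy as np
import pandas as pd
import pytest

import lordquant as lq
from lordquant.imaging_io import EyeAnatomy


@pytest.fixture
def coarse_anatomy() -> EyeAnatomy:
    """Right-eye anatomy on a small raster (coarse pixel scale)."""
    return EyeAnatomy(fovea_xy=(150.0, 256.0), onh_xy=(370.0, 276.0), pixel_scale=21.0,
                      laterality="right")


@pytest.fixture(scope="session")
def small_cohort() -> lq.SyntheticCohort:
    """Fully rendered three-patient cohort used across image-level tests."""
    cfg = lq.CohortConfig(
        n_patients=3, image_size=512, pixel_scale_range=(21.0, 22.0), seed=11
    )
    return lq.generate_cohort(cfg)


@pytest.fixture(scope="session")
def stats_cohort() -> lq.SyntheticCohort:
    """Larger cohort without image rendering (trajectories/ledger only)."""
    cfg = lq.CohortConfig(n_patients=16, seed=5)
    return lq.generate_cohort(cfg, render_images=False)


def hinge_frame(params, rng, n_patients=16, n_visits=5, age_lo=None, age_hi=None):
    """Pooled long-format metric table from planted hinge trajectories."""
    from lordquant.synthetic_cohort import hinge_mean

    psi = params.breakpoint_age
    age_lo = psi - 12 if age_lo is None else age_lo
    age_hi = psi + 8 if age_hi is None else age_hi
    rows = []
    for p in range(n_patients):
        u_p = rng.normal(0, params.patient_intercept_sd)
        ages = rng.uniform(age_lo, age_hi) + np.arange(n_visits) * rng.uniform(1.0, 1.6)
        for eye in ("OD", "OS"):
            u_e = rng.normal(0, params.eye_intercept_sd)
            vals = hinge_mean(params, ages) + u_p + u_e + rng.normal(
                0, params.residual_sd, n_visits
            )
            for a, v in zip(ages, vals):
                rows.append(dict(patient_id=f"P{p}", eye=eye, age_years=a, value=v))
    return pd.DataFrame(rows)
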