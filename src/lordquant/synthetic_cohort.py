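"""Synthetic longitudinal retinal-imaging cohort with known ground truth.

The generator emulates the statistical and spatial structure the analysis
assumes in C1QTNF5 late-onset retinal degeneration (LORD):

* hinge-shaped metric trajectories — flat until an inflection age psi,
  then linear change — with patient- and eye-level random intercepts and
  high interocular correlation (shared patient intercept plus a
  configurable shared fraction of the visit-level residual trajectory);
* scalloped atrophy masks seeded in the temporal retina that expand
  nasally as the target area grows, nested across visits;
* anatomical variability in fovea-disc distance, vertical disc offset
  and pixel scale, so every eye needs its own shear and superpixel size;
* planted projective misregistration of follow-up images, with exact
  corresponding control points, to exercise the registration stage;
* a clinical BCVA table with occasional qualitative end-stage codes.

Every generated exam has exactly one row in the ground-truth ledger, and
all randomness flows through one seeded generator with per-eye
substreams, so a config fully determines all outputs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CapacityError, InvalidConfigError, ValidationError
from .imaging_io import LEFT, RIGHT, EyeAnatomy, FAFExam, mirror_x
from .quantification import OCTFoveaScan
from .registration import ControlPointSet, Homography

# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HingeParams:
    """Ground-truth hinge trajectory for one metric.

    ``value(age) = intercept_at_breakpoint + pre_slope*min(age-psi, 0)
    + post_slope*max(age-psi, 0)`` plus patient intercept, eye intercept
    and visit-level residual noise.
    """

    breakpoint_age: float
    pre_slope: float
    post_slope: float
    intercept_at_breakpoint: float
    patient_intercept_sd: float = 0.0
    eye_intercept_sd: float = 0.0
    residual_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("patient_intercept_sd", "eye_intercept_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")


def default_metric_params() -> dict[str, HingeParams]:
    """Study-condition trajectories: breakpoints and post-inflection rates
    at the cohort-level estimates for this disease; variance components
    are free generator parameters (see docs/methods.md)."""
    return {
        # sqrt area of atrophy (mm): no atrophy before the inflection
        "sqrtAA_14mm": HingeParams(53.9, 0.0, 0.53, 0.0, 0.5, 0.3, 0.3),
        "sqrtAA_6mm": HingeParams(56.3, 0.0, 0.24, 0.0, 0.3, 0.15, 0.15),
        # EZ width (µm): intact scan-wide before loss begins
        "EZ_total": HingeParams(50.8, 0.0, -257.0, 6000.0, 300.0, 150.0, 150.0),
        # foveal thicknesses (µm)
        "CRT": HingeParams(62.3, 0.0, -4.7, 280.0, 20.0, 10.0, 8.0),
        "PR_RPE": HingeParams(60.0, 0.0, -3.8, 110.0, 15.0, 8.0, 6.0),
        # visual acuity (LogMAR, larger = worse)
        "BCVA_logMAR": HingeParams(70.3, 0.0, 0.05, 0.1, 0.1, 0.05, 0.05),
    }


@dataclass
class CohortConfig:
    """Shape and conditions of the simulated cohort.

    ``visit_ages`` may list explicit per-patient visit ages; when None,
    each patient gets a baseline age and visit spacings drawn to mimic a
    natural-history clinic series (median follow-up about five years).
    """

    n_patients: int = 16
    eyes_per_patient: int = 2
    visit_ages: list[list[float]] | None = None
    metrics: dict[str, HingeParams] = field(default_factory=default_metric_params)
    interocular_latent_share: float = 0.8
    image_size: int = 1024
    pixel_scale_range: tuple[float, float] = (10.0, 11.0)
    fovea_disc_distance_range: tuple[float, float] = (4400.0, 4900.0)
    peripapillary_fraction: float = 0.3
    max_shift_px: float = 12.0
    n_control_points: int = 9
    endstage_injection_rate: float = 0.05
    scan_half_extent_um: float = 3600.0
    ascan_spacing_um: float = 12.0
    baseline_age_range: tuple[float, float] = (52.0, 68.0)
    visits_range: tuple[int, int] = (2, 6)
    visit_spacing_range: tuple[float, float] = (0.8, 1.8)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise InvalidConfigError("n_patients must be >= 1")
        if self.eyes_per_patient not in (1, 2):
            raise InvalidConfigError("eyes_per_patient must be 1 or 2")
        if not 0.0 <= self.interocular_latent_share <= 1.0:
            raise InvalidConfigError("interocular_latent_share must lie in [0, 1]")
        if self.visit_ages is not None:
            if len(self.visit_ages) != self.n_patients:
                raise InvalidConfigError("visit_ages must list one series per patient")
            for ages in self.visit_ages:
                if np.any(np.diff(ages) <= 0):
                    raise InvalidConfigError("visit ages must be strictly increasing")


# ---------------------------------------------------------------------------
# Seed plumbing
# ---------------------------------------------------------------------------


def eye_rng(seed: int, patient: int, eye_index: int, purpose: int = 0) -> np.random.Generator:
    """Stable per-(patient, eye, purpose) substream of the cohort seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(patient), int(eye_index), int(purpose)]))


# ---------------------------------------------------------------------------
# Anatomy
# ---------------------------------------------------------------------------


def generate_anatomy(
    config: CohortConfig, patient: int, eye_index: int, rng: np.random.Generator | None = None
) -> EyeAnatomy:
    """Sample one eye's landmark anatomy.

    Right-eye convention: ONH strictly nasal (larger x) of the fovea;
    left eyes (``eye_index == 1``) are generated mirrored about the image
    midline.  The vertical fovea-disc offset is nonzero so the shear
    stage has real work to do.
    """
    rng = rng or eye_rng(config.seed, patient, eye_index, purpose=1)
    scale = rng.uniform(*config.pixel_scale_range)
    dist_um = rng.uniform(*config.fovea_disc_distance_range)
    dist_px = dist_um / scale
    if dist_px < 1.0:
        raise InvalidConfigError("fovea-disc distance not representable at this pixel scale")
    if config.image_size < 2 * dist_px:
        raise InvalidConfigError(
            f"image size {config.image_size} px < 2x fovea-disc distance {dist_px:.0f} px"
        )
    w = h = config.image_size
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    fovea = (cx - dist_px / 2.0 + rng.uniform(-10, 10), cy + rng.uniform(-15, 15))
    dy = rng.uniform(-0.10, 0.10) * dist_px
    dx = math.sqrt(max(dist_px**2 - dy**2, 1.0))
    onh = (fovea[0] + dx, fovea[1] + dy)
    laterality = RIGHT if eye_index == 0 else LEFT
    if laterality == LEFT:
        fovea, onh = mirror_x(fovea, w), mirror_x(onh, w)
    anatomy = EyeAnatomy(fovea_xy=fovea, onh_xy=onh, pixel_scale=scale, laterality=laterality)
    for x, y in (anatomy.fovea_xy, anatomy.onh_xy):
        if not (0 <= x < w and 0 <= y < h):
            raise InvalidConfigError("generated landmarks fall outside the raster")
    return anatomy


# ---------------------------------------------------------------------------
# Hinge trajectories
# ---------------------------------------------------------------------------


def hinge_mean(params: HingeParams, ages) -> np.ndarray:
    """Noise-free hinge trajectory at the given ages."""
    a = np.asarray(ages, dtype=float)
    d = a - params.breakpoint_age
    return (
        params.intercept_at_breakpoint
        + params.pre_slope * np.minimum(d, 0.0)
        + params.post_slope * np.maximum(d, 0.0)
    )


def simulate_hinge_series(
    params: HingeParams,
    ages,
    rng: np.random.Generator,
    u_patient: float | None = None,
    shared_resid: np.ndarray | None = None,
    shared_fraction: float = 0.0,
) -> np.ndarray:
    """One eye's noisy metric series.

    ``u_patient`` (the patient random intercept) and ``shared_resid``
    (standard-normal visit deviations common to fellow eyes) may be
    passed in so both eyes of a patient share them; ``shared_fraction``
    is the share of residual variance carried by the common component,
    which together with the shared intercept induces the interocular
    correlation.
    """
    ages = np.asarray(ages, dtype=float)
    if np.any(np.diff(ages) < 0):
        raise ValidationError("ages must be sorted")
    if u_patient is None:
        u_patient = rng.normal(0.0, params.patient_intercept_sd)
    u_eye = rng.normal(0.0, params.eye_intercept_sd) if params.eye_intercept_sd > 0 else 0.0
    z_own = rng.standard_normal(len(ages))
    if shared_resid is not None and shared_fraction > 0:
        z = math.sqrt(shared_fraction) * np.asarray(shared_resid) + math.sqrt(
            1.0 - shared_fraction
        ) * z_own
    else:
        z = z_own
    return hinge_mean(params, ages) + u_patient + u_eye + params.residual_sd * z


def eye_noise_sd_for_target_r(trajectory: np.ndarray, target_r: float) -> float:
    """Closed-form calibration of independent per-eye noise so the true
    within-subject correlation between fellow eyes equals ``target_r``.

    Fellow eyes share the within-patient trajectory deviation; with
    independent per-eye noise of variance ``s2``, the within-subject
    correlation is ``var_w / (var_w + s2)`` where ``var_w`` is the
    variance of the shared trajectory about its within-patient mean.
    """
    if not 0 < target_r <= 1:
        raise ValidationError("target correlation must lie in (0, 1]")
    var_w = float(np.var(np.asarray(trajectory, dtype=float)))
    if var_w == 0:
        raise ValidationError("trajectory has no within-patient variation to correlate")
    return math.sqrt(var_w * (1.0 - target_r) / target_r)


# ---------------------------------------------------------------------------
# Atrophy mask rendering
# ---------------------------------------------------------------------------


def _paint_disc(
    mask: np.ndarray, cx: float, cy: float, r: float, allowed: np.ndarray | None = None
) -> int:
    """Paint a disc (clipped to ``allowed``); return newly set pixels."""
    h, w = mask.shape
    x0, x1 = max(int(cx - r) - 1, 0), min(int(cx + r) + 2, w)
    y0, y1 = max(int(cy - r) - 1, 0), min(int(cy + r) + 2, h)
    if x0 >= x1 or y0 >= y1:
        return 0
    yy, xx = np.ogrid[y0:y1, x0:x1]
    disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    if allowed is not None:
        disc &= allowed[y0:y1, x0:x1]
    sub = mask[y0:y1, x0:x1]
    new = int(np.count_nonzero(disc & ~sub))
    sub |= disc
    return new


def _disc_sequence(
    anatomy: EyeAnatomy,
    rng: np.random.Generator,
    shape: tuple[int, int],
    confine_radius_px: float,
):
    """Deterministic lobe sequence for scalloped-atrophy growth.

    The first disc seeds temporal to the fovea; each subsequent lobe
    branches off an earlier disc centre (mostly a recent one, so growth
    has a frontier) with a nasally biased offset, confined to the
    fovea-centred measurement circle.  The sequence depends only on the
    generator state, never on how many discs a caller consumes, so masks
    built from prefixes of one sequence are nested.

    Yields (cx, cy, radius) indefinitely.
    """
    h, w = shape
    fx, fy = anatomy.fovea_xy
    dist = abs(anatomy.onh_xy[0] - anatomy.fovea_xy[0])
    nasal_sign = 1.0 if anatomy.onh_xy[0] > fx else -1.0
    r_lo, r_hi = 0.04 * dist, 0.10 * dist

    def _confine(x: float, y: float) -> tuple[float, float]:
        dx, dy = x - fx, y - fy
        d = math.hypot(dx, dy)
        lim = confine_radius_px - 1.0
        if d > lim:
            x, y = fx + dx * lim / d, fy + dy * lim / d
        return float(np.clip(x, 0, w - 1)), float(np.clip(y, 0, h - 1))

    # seed in the temporal retina (opposite side from the ONH)
    x, y = _confine(
        fx - nasal_sign * min(0.9 * dist, 0.8 * confine_radius_px) + rng.normal(0, 0.05 * dist),
        fy + rng.normal(0, 0.15 * dist),
    )
    centers: list[tuple[float, float]] = []
    while True:
        r = rng.uniform(r_lo, r_hi)
        if centers:
            if rng.random() < 0.7:
                k = len(centers) - 1 - int(rng.integers(0, min(len(centers), 20)))
            else:
                k = int(rng.integers(0, len(centers)))
            px, py = centers[k]
            x, y = _confine(
                px + nasal_sign * rng.normal(0.35, 0.6) * r,
                py + rng.normal(0.0, 0.9) * r,
            )
        centers.append((x, y))
        yield x, y, r


def _grow_ring(
    mask: np.ndarray, allowed: np.ndarray, target_px: float, nasal_sign: float
) -> tuple[int, bool]:
    """Add boundary-ring pixels in a fixed (temporal-first) order until
    the target is met or the ring is exhausted.

    Returns (pixel count after growth, target reached).  A count of -1
    signals that the allowed region is already completely filled.
    """
    from scipy import ndimage

    ring = ndimage.binary_dilation(mask) & allowed & ~mask
    ys, xs = np.nonzero(ring)
    if ys.size == 0:
        return -1, False
    count = int(np.count_nonzero(mask))
    need = int(math.ceil(target_px)) - count
    order = np.lexsort((ys, nasal_sign * xs))
    take = min(need, ys.size)
    mask[ys[order[:take]], xs[order[:take]]] = True
    count += take
    return count, count >= target_px


def render_atrophy_mask(
    anatomy: EyeAnatomy,
    target_area_mm2: float,
    rng: np.random.Generator,
    shape: tuple[int, int],
    confine_diameter_mm: float = 14.0,
    exclude: np.ndarray | None = None,
    tol: float = 0.005,
    max_discs: int = 60000,
) -> np.ndarray:
    """Render a scalloped atrophy mask of (approximately) a target area.

    The mask is the union of overlapping discs laid down by a seeded
    random walk starting temporal to the fovea and drifting nasally, so
    increasing target areas give nested masks for a fixed seed, the lobed
    boundary mimics scalloped atrophy, and growth is temporal-to-nasal.
    Painting is confined to the fovea-centred measurement circle
    (``confine_diameter_mm``) so the realised area equals the area the
    quantification stage will measure.  The final lobe's radius is tuned
    by bisection so the realised pixel area lands within ``tol`` (0.5%)
    of the target.
    """
    if target_area_mm2 < 0:
        raise ValidationError("target area must be >= 0")
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    if target_area_mm2 == 0:
        return mask
    px_area_mm2 = anatomy.pixel_scale**2 / 1e6
    target_px = target_area_mm2 / px_area_mm2
    fx, fy = anatomy.fovea_xy
    radius_px = (confine_diameter_mm * 1000.0 / 2.0) / anatomy.pixel_scale
    yy, xx = np.ogrid[:h, :w]
    allowed = (xx - fx) ** 2 + (yy - fy) ** 2 <= radius_px**2
    if exclude is not None:
        # e.g. the peripapillary annulus: excluded from measurement, so
        # excluded from planting to keep target and measured area equal
        allowed &= ~np.asarray(exclude, dtype=bool)
    capacity = int(np.count_nonzero(allowed))
    if target_px > capacity:
        raise CapacityError(
            f"target {target_area_mm2:.1f} mm^2 exceeds the {capacity * px_area_mm2:.1f} mm^2 "
            "available inside the measurement circle"
        )
    nasal_sign = 1.0 if anatomy.onh_xy[0] > fx else -1.0
    walk = _disc_sequence(anatomy, rng, shape, radius_px)
    count = 0
    stagnant = 0
    for _ in range(max_discs):
        cx, cy, r = next(walk)
        if count + math.pi * (r + 1.0) ** 2 < target_px:
            # cannot overshoot: paint in place
            added = _paint_disc(mask, cx, cy, r, allowed)
            count += added
            stagnant = stagnant + 1 if added == 0 else 0
            if stagnant >= 50:
                # lobe growth has saturated; advance by one boundary ring,
                # temporal pixels first (fixed order keeps masks nested)
                count, reached = _grow_ring(mask, allowed, target_px, nasal_sign)
                stagnant = 0
                if reached:
                    return mask
                if count < 0:
                    break  # allowed region completely filled
            continue
        before = mask.copy()
        added = _paint_disc(mask, cx, cy, r, allowed)
        count += added
        if count < target_px:
            stagnant = stagnant + 1 if added == 0 else 0
            if stagnant >= 50:
                count, reached = _grow_ring(mask, allowed, target_px, nasal_sign)
                stagnant = 0
                if reached:
                    return mask
                if count < 0:
                    break
            continue
        if count >= target_px:
            # tune the last lobe's radius so the realised area hits the target
            lo, hi = 0.0, r
            best = mask
            for _ in range(40):
                mid = 0.5 * (lo + hi)
                trial = before.copy()
                c = int(np.count_nonzero(before)) + _paint_disc(trial, cx, cy, mid, allowed)
                if c >= target_px:
                    best, hi = trial, mid
                else:
                    lo = mid
                if abs(c - target_px) <= max(1.0, tol * target_px):
                    best = trial
                    break
            return best
    raise CapacityError("disc budget exhausted before reaching the target area")


def atrophy_capacity_mm2(
    anatomy: EyeAnatomy,
    shape: tuple[int, int],
    diameter_mm: float = 14.0,
    exclude: np.ndarray | None = None,
) -> float:
    """Area (mm^2) available inside the fovea-centred measurement circle
    clipped to the raster — the ceiling any atrophy target can reach."""
    h, w = shape
    fx, fy = anatomy.fovea_xy
    radius_px = (diameter_mm * 1000.0 / 2.0) / anatomy.pixel_scale
    yy, xx = np.ogrid[:h, :w]
    allowed = (xx - fx) ** 2 + (yy - fy) ** 2 <= radius_px**2
    if exclude is not None:
        allowed &= ~np.asarray(exclude, dtype=bool)
    return float(np.count_nonzero(allowed)) * anatomy.pixel_scale**2 / 1e6


def render_peripapillary_mask(
    anatomy: EyeAnatomy, rng: np.random.Generator, shape: tuple[int, int]
) -> np.ndarray:
    """Annulus of peripapillary atrophy around the ONH (present in a
    configurable fraction of eyes; exercises the exclusion rule)."""
    h, w = shape
    onh_radius_px = 850.0 / anatomy.pixel_scale  # ~1.7 mm disc diameter
    r_in = onh_radius_px * rng.uniform(0.9, 1.1)
    r_out = r_in + onh_radius_px * rng.uniform(0.2, 0.5)
    ox, oy = anatomy.onh_xy
    yy, xx = np.ogrid[:h, :w]
    d2 = (xx - ox) ** 2 + (yy - oy) ** 2
    return (d2 >= r_in**2) & (d2 <= r_out**2)


def render_faf_image(
    anatomy: EyeAnatomy,
    atrophy_mask: np.ndarray,
    peripapillary_mask: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Schematic FAF intensity raster: mid-grey background with mild
    noise, hypo-autofluorescent (dark) atrophy, and a dark disc at the
    ONH.  No attempt at photorealistic texture."""
    h, w = atrophy_mask.shape
    img = 0.55 + 0.05 * rng.standard_normal((h, w))
    img[atrophy_mask] = 0.12
    img[peripapillary_mask] = 0.20
    ox, oy = anatomy.onh_xy
    onh_radius_px = 850.0 / anatomy.pixel_scale
    yy, xx = np.ogrid[:h, :w]
    img[(xx - ox) ** 2 + (yy - oy) ** 2 <= onh_radius_px**2] = 0.08
    return np.clip(img, 0.0, 1.0).astype(np.float32)


# ---------------------------------------------------------------------------
# Follow-up misregistration
# ---------------------------------------------------------------------------


def random_homography(
    shape: tuple[int, int], max_shift: float, rng: np.random.Generator
) -> Homography:
    """Mild projective transform built by displacing the four frame
    corners by up to ``max_shift`` px (follow-up -> baseline map)."""
    if max_shift == 0:
        return Homography.identity()
    h, w = shape
    base = np.array([[0, 0], [w - 1.0, 0], [w - 1.0, h - 1.0], [0, h - 1.0]])
    follow = base + rng.uniform(-max_shift, max_shift, size=(4, 2))
    from skimage.transform import ProjectiveTransform

    tform = ProjectiveTransform.from_estimate(src=follow, dst=base)
    if not tform:
        return Homography.identity()
    return Homography(tform.params)


def control_points_for(
    h_planted: Homography, shape: tuple[int, int], n_points: int = 9
) -> ControlPointSet:
    """Exact corresponding point pairs consistent with the planted
    homography: a non-collinear interior grid of baseline points and
    their preimages in the follow-up frame."""
    if n_points < 4:
        raise ValidationError("at least 4 control points required")
    hh, ww = shape
    side = max(3, math.ceil(math.sqrt(n_points)))
    xs = np.linspace(0.15 * ww, 0.85 * ww, side)
    ys = np.linspace(0.15 * hh, 0.85 * hh, side)
    gx, gy = np.meshgrid(xs, ys)
    base = np.column_stack([gx.ravel(), gy.ravel()])[:n_points]
    follow = h_planted.inverse().apply(base)
    return ControlPointSet(base=base, follow=follow)


def perturb_followup(
    exam: FAFExam,
    max_shift: float,
    rng: np.random.Generator,
    n_points: int = 9,
) -> tuple[FAFExam, ControlPointSet, Homography]:
    """Misalign a follow-up exam by a random planted projective transform.

    Returns the warped exam, >= ``n_points`` exact corresponding control
    points (reprojection error ~ machine precision), and the planted
    homography mapping follow-up coordinates back onto baseline.
    """
    from .registration import apply_transform

    h_planted = random_homography(exam.shape, max_shift, rng)
    if max_shift == 0:
        warped = exam
    else:
        inv = h_planted.inverse()
        warped = dataclasses.replace(
            exam,
            image=apply_transform(exam.image, inv, kind="image"),
            atrophy_mask=apply_transform(exam.atrophy_mask, inv, kind="mask"),
            peripapillary_mask=apply_transform(exam.peripapillary_mask, inv, kind="mask"),
        )
    points = control_points_for(h_planted, exam.shape, n_points)
    return warped, points, h_planted


# ---------------------------------------------------------------------------
# OCT scans and BCVA
# ---------------------------------------------------------------------------


def synthesize_oct_scan(
    ez_total_um: float,
    crt_um: float,
    pr_rpe_um: float,
    rng: np.random.Generator,
    half_extent_um: float = 3600.0,
    spacing_um: float = 12.0,
    nasal_fraction: float | None = None,
) -> OCTFoveaScan:
    """Foveal B-scan derivative with a planted EZ extent and layer heights.

    The intact EZ region spans from ``-temporal`` to ``+nasal`` around
    the fovea where nasal + temporal = ez_total (split by
    ``nasal_fraction``, random near 0.5 by default).  A sub-threshold
    single-sample dropout is occasionally planted inside the intact
    region to exercise the clear-loss rule.
    """
    n = int(round(half_extent_um / spacing_um))
    lateral = np.arange(-n, n + 1) * spacing_um
    ez_total_um = float(np.clip(ez_total_um, 0.0, 2 * half_extent_um))
    if nasal_fraction is None:
        nasal_fraction = rng.uniform(0.4, 0.6)
    nasal = min(ez_total_um * nasal_fraction, half_extent_um)
    temporal = min(ez_total_um - nasal, half_extent_um)
    intact = (lateral >= -temporal - 1e-9) & (lateral <= nasal + 1e-9)
    if ez_total_um == 0:
        intact[:] = False
    elif rng.random() < 0.3:
        interior = np.flatnonzero(intact[1:-1]) + 1
        interior = interior[np.abs(lateral[interior]) > 2 * spacing_um]
        if interior.size:
            intact[rng.choice(interior)] = False  # attenuation artefact, extent < 2 a-scans
    ilm = 100.0
    crt_um = max(crt_um, 0.0)
    pr_rpe_um = float(np.clip(pr_rpe_um, 0.0, crt_um))
    return OCTFoveaScan(
        lateral_um=lateral,
        ez_intact=intact,
        ilm_um=ilm,
        elm_um=ilm + crt_um - pr_rpe_um,
        rpe_brm_um=ilm + crt_um,
    )


def bcva_entry(true_logmar: float, rng: np.random.Generator, injection_rate: float) -> str:
    """Clinical-table BCVA entry: numeric LogMAR, or an occasional
    counting-fingers code standing in for an unquantifiable acuity."""
    if rng.random() < injection_rate:
        return "CF"
    return f"{true_logmar:.2f}"


# ---------------------------------------------------------------------------
# Whole-cohort generation
# ---------------------------------------------------------------------------


@dataclass
class ExamArtifact:
    """One generated FAF exam plus its registration payload."""

    exam: FAFExam  # misaligned for follow-ups, baseline frame for visit 0
    control_points: ControlPointSet | None
    planted_homography: Homography | None
    visit: int


@dataclass
class SyntheticCohort:
    exams: list[ExamArtifact]
    oct_scans: list[tuple[str, str, float, OCTFoveaScan]]  # patient, eye, age, scan
    clinical: pd.DataFrame
    ledger: pd.DataFrame
    config: CohortConfig


def _visit_ages(config: CohortConfig, patient: int, rng: np.random.Generator) -> np.ndarray:
    if config.visit_ages is not None:
        return np.asarray(config.visit_ages[patient], dtype=float)
    baseline = rng.uniform(*config.baseline_age_range)
    n_visits = int(rng.integers(config.visits_range[0], config.visits_range[1] + 1))
    gaps = rng.uniform(*config.visit_spacing_range, size=n_visits - 1)
    return baseline + np.concatenate([[0.0], np.cumsum(gaps)])


def generate_cohort(config: CohortConfig, render_images: bool = True) -> SyntheticCohort:
    """Generate the full synthetic cohort.

    Both eyes of a patient share visit ages, the patient-level random
    intercept and a ``interocular_latent_share`` fraction of the
    visit-level residual trajectory.  Mask target areas follow the
    planted sqrt-AA(14 mm) trajectory squared, forced non-decreasing over
    visits so masks are nested; follow-up exams are warped by a planted
    homography and shipped with exact control points.  With
    ``render_images=False`` only trajectories, OCT scans, the clinical
    table and the ledger are produced (fast path for statistical work).
    """
    exams: list[ExamArtifact] = []
    scans: list[tuple[str, str, float, OCTFoveaScan]] = []
    clinical_rows: list[dict] = []
    ledger_rows: list[dict] = []
    shape = (config.image_size, config.image_size)
    eye_labels = {0: "OD", 1: "OS"}
    for p in range(config.n_patients):
        patient_id = f"P{p:03d}"
        prng = eye_rng(config.seed, p, 0, purpose=0)
        ages = _visit_ages(config, p, prng)
        shared: dict[str, tuple[float, np.ndarray]] = {}
        for name, params in config.metrics.items():
            shared[name] = (
                prng.normal(0.0, params.patient_intercept_sd),
                prng.standard_normal(len(ages)),
            )
        for e in range(config.eyes_per_patient):
            eye = eye_labels[e]
            rng = eye_rng(config.seed, p, e, purpose=2)
            anatomy = generate_anatomy(config, p, e)
            series = {
                name: simulate_hinge_series(
                    params,
                    ages,
                    rng,
                    u_patient=shared[name][0],
                    shared_resid=shared[name][1],
                    shared_fraction=config.interocular_latent_share,
                )
                for name, params in config.metrics.items()
            }
            sqrt_aa = np.maximum(series.get("sqrtAA_14mm", np.zeros(len(ages))), 0.0)
            has_peri = rng.random() < config.peripapillary_fraction
            peri = (
                render_peripapillary_mask(anatomy, rng, shape)
                if (has_peri and render_images)
                else np.zeros(shape, dtype=bool)
            )
            # nested masks need non-decreasing targets; atrophy saturates
            # at the measurement-circle capacity like the real quantity
            cap = (
                0.95 * atrophy_capacity_mm2(anatomy, shape, exclude=peri)
                if render_images
                else math.inf
            )
            aa_targets = np.minimum(np.maximum.accumulate(sqrt_aa**2), cap)
            mask_seed = np.random.SeedSequence([int(config.seed), p, e, 3])
            warp_rng = eye_rng(config.seed, p, e, purpose=4)
            img_rng = eye_rng(config.seed, p, e, purpose=5)
            for v, age in enumerate(ages):
                exam_id = f"{patient_id}_{eye}_v{v}"
                realized_aa14 = realized_aa6 = float("nan")
                points = h_planted = None
                if render_images:
                    # a fresh generator from the per-eye mask seed every
                    # visit replays the same lobe sequence => nested masks
                    mrng = np.random.default_rng(mask_seed)
                    atrophy = render_atrophy_mask(
                        anatomy, float(aa_targets[v]), mrng, shape, exclude=peri
                    )
                    from .quantification import area_of_atrophy

                    realized_aa14 = area_of_atrophy(atrophy, peri, anatomy, 14.0).aa_mm2
                    realized_aa6 = area_of_atrophy(atrophy, peri, anatomy, 6.0).aa_mm2
                    image = render_faf_image(anatomy, atrophy, peri, img_rng)
                    exam = FAFExam(
                        image=image,
                        atrophy_mask=atrophy,
                        peripapillary_mask=peri,
                        anatomy=anatomy,
                        patient_id=patient_id,
                        eye=eye,
                        age_at_exam=float(age),
                        field_of_view="55",
                        exam_id=exam_id,
                    )
                    if v > 0:
                        exam, points, h_planted = perturb_followup(
                            exam, config.max_shift_px, warp_rng, config.n_control_points
                        )
                    exams.append(
                        ExamArtifact(
                            exam=exam, control_points=points, planted_homography=h_planted, visit=v
                        )
                    )
                ez = float(series["EZ_total"][v]) if "EZ_total" in series else float("nan")
                crt = float(series["CRT"][v]) if "CRT" in series else float("nan")
                prr = float(series["PR_RPE"][v]) if "PR_RPE" in series else float("nan")
                if not math.isnan(ez):
                    scans.append(
                        (
                            patient_id,
                            eye,
                            float(age),
                            synthesize_oct_scan(
                                ez,
                                crt if not math.isnan(crt) else 250.0,
                                prr if not math.isnan(prr) else 90.0,
                                rng,
                                half_extent_um=config.scan_half_extent_um,
                                spacing_um=config.ascan_spacing_um,
                            ),
                        )
                    )
                bcva_true = float(series["BCVA_logMAR"][v]) if "BCVA_logMAR" in series else float("nan")
                if not math.isnan(bcva_true):
                    clinical_rows.append(
                        {
                            "patient_id": patient_id,
                            "eye": eye,
                            "age_years": float(age),
                            "bcva": bcva_entry(bcva_true, rng, config.endstage_injection_rate),
                        }
                    )
                row = {
                    "exam_id": exam_id,
                    "patient_id": patient_id,
                    "eye": eye,
                    "visit": v,
                    "age_years": float(age),
                    "aa14_target_mm2": float(aa_targets[v]),
                    "aa14_true_mm2": realized_aa14,
                    "aa6_true_mm2": realized_aa6,
                    "ez_total_true_um": ez,
                    "crt_true_um": crt,
                    "pr_rpe_true_um": prr,
                    "bcva_true_logmar": bcva_true,
                    "u_patient_sqrt_aa14": shared.get("sqrtAA_14mm", (float("nan"),))[0],
                    "has_peripapillary": bool(has_peri),
                    "planted_homography": ""
                    if h_planted is None
                    else ";".join(f"{v_:.12g}" for v_ in h_planted.to_row()),
                }
                for name in config.metrics:
                    row[f"true_{name}"] = float(series[name][v])
                ledger_rows.append(row)
    ledger = pd.DataFrame(ledger_rows)
    clinical = pd.DataFrame(clinical_rows, columns=["patient_id", "eye", "age_years", "bcva"])
    return SyntheticCohort(
        exams=exams, oct_scans=scans, clinical=clinical, ledger=ledger, config=config
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Persist a cohort: TIFF rasters + JSON sidecars per exam, control
    points as CSV, and clinical table / ground-truth ledger as CSV."""
    from pathlib import Path

    from .imaging_io import save_exam

    outdir = Path(outdir)
    (outdir / "exams").mkdir(parents=True, exist_ok=True)
    for art in cohort.exams:
        save_exam(art.exam, outdir / "exams", stem=art.exam.exam_id)
        if art.control_points is not None:
            art.control_points.to_csv(outdir / "exams" / f"{art.exam.exam_id}_points.csv")
    cohort.clinical.to_csv(outdir / "clinical.csv", index=False)
    cohort.ledger.to_csv(outdir / "ledger.csv", index=False)
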