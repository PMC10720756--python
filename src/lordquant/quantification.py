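"""Scalar clinical metrics: circle-restricted area of atrophy, EZ width,
foveal thicknesses, and BCVA conversion to LogMAR.

Area of atrophy (AA) is measured in the registered but *unsheared* frame
within fovea-centred circles of 6 mm (central ETDRS circle) and 14 mm
(largest circle inside a 55-degree field) diameter, peripapillary atrophy
excluded, and is square-root transformed for progression analysis to
decouple growth rates from baseline lesion size.

EZ (ellipsoid zone) width is the sum of the nasal and temporal distances
from the fovea to the first *clear* EZ break on each side; isolated
dropouts shorter than ``min_break_extent`` count as signal attenuation,
not loss.  Foveal thicknesses are strictly vertical distances between
layer boundaries at lateral position 0: CRT from the internal limiting
membrane (ILM) to the posterior RPE-Bruch's boundary, PR+RPE from the
external limiting membrane (ELM) to the same posterior boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ShapeMismatchError, ValidationError
from .imaging_io import EyeAnatomy

#: Circle diameters (mm) used for AA quantification.
AA_DIAMETERS_MM = (6.0, 14.0)

#: Qualitative end-stage visual-acuity codes and their LogMAR values.
BCVA_CODES = {"CF": 2.6, "HM": 2.7, "LP": 2.8, "NLP": 2.9}

METRIC_UNITS = {
    "sqrtAA_6mm": "mm",
    "sqrtAA_14mm": "mm",
    "AA_6mm": "mm^2",
    "AA_14mm": "mm^2",
    "EZ_total": "um",
    "EZ_nasal": "um",
    "EZ_temporal": "um",
    "CRT": "um",
    "PR_RPE": "um",
    "BCVA_logMAR": "LogMAR",
}


@dataclass(frozen=True)
class OCTFoveaScan:
    """Foveal B-scan derivatives.

    Parameters
    ----------
    lateral_um : array
        Strictly increasing lateral positions relative to the fovea
        (negative temporal, positive nasal); position 0 must be sampled.
    ez_intact : bool array
        EZ integrity at each lateral sample.
    ilm_um, elm_um, rpe_brm_um : float or NaN
        Axial boundary heights at the fovea (any common origin; only
        differences matter).  NaN marks a missing boundary.
    """

    lateral_um: np.ndarray
    ez_intact: np.ndarray
    ilm_um: float = math.nan
    elm_um: float = math.nan
    rpe_brm_um: float = math.nan

    def __post_init__(self) -> None:
        lat = np.asarray(self.lateral_um, dtype=float)
        intact = np.asarray(self.ez_intact, dtype=bool)
        if lat.ndim != 1 or lat.shape != intact.shape:
            raise ValidationError("lateral axis and EZ trace must be matching 1-D arrays")
        if not np.all(np.diff(lat) > 0):
            raise ValidationError("lateral axis must be strictly increasing")
        if not np.any(np.isclose(lat, 0.0)):
            raise ValidationError("fovea (lateral position 0) must be sampled")
        object.__setattr__(self, "lateral_um", lat)
        object.__setattr__(self, "ez_intact", intact)

    @property
    def spacing_um(self) -> float:
        """Median a-scan spacing."""
        return float(np.median(np.diff(self.lateral_um)))

    @property
    def fovea_index(self) -> int:
        return int(np.argmin(np.abs(self.lateral_um)))


@dataclass(frozen=True)
class AreaResult:
    aa_mm2: float
    sqrt_aa_mm: float
    diameter_mm: float
    truncated: bool = False  # circle extended beyond the imaged field


def area_of_atrophy(
    atrophy_mask: np.ndarray,
    peripapillary_mask: np.ndarray | None,
    anatomy: EyeAnatomy,
    diameter_mm: float,
) -> AreaResult:
    """Area of atrophy within a fovea-centred circle.

    ``AA = (# atrophy pixels inside the circle, peripapillary excluded)
    * pixel_scale^2 / 1e6`` in mm^2; circle membership is by pixel-centre
    distance <= diameter/2 in micrometres.  When the circle extends past
    the raster the result is computed on the available field and flagged
    ``truncated``.
    """
    if diameter_mm <= 0:
        raise ValidationError("circle diameter must be positive")
    atrophy_mask = np.asarray(atrophy_mask).astype(bool)
    h, w = atrophy_mask.shape
    if peripapillary_mask is not None:
        peripapillary_mask = np.asarray(peripapillary_mask).astype(bool)
        if peripapillary_mask.shape != atrophy_mask.shape:
            raise ShapeMismatchError("peripapillary mask shape differs from atrophy mask")
        atrophy_mask = atrophy_mask & ~peripapillary_mask
    fx, fy = anatomy.fovea_xy
    radius_px = (diameter_mm * 1000.0 / 2.0) / anatomy.pixel_scale
    yy, xx = np.ogrid[:h, :w]
    inside = (xx - fx) ** 2 + (yy - fy) ** 2 <= radius_px**2
    truncated = (
        fx - radius_px < -0.5
        or fy - radius_px < -0.5
        or fx + radius_px > w - 0.5
        or fy + radius_px > h - 0.5
    )
    count = int(np.count_nonzero(atrophy_mask & inside))
    aa = count * anatomy.pixel_scale**2 / 1e6
    return AreaResult(
        aa_mm2=aa, sqrt_aa_mm=math.sqrt(aa), diameter_mm=float(diameter_mm), truncated=truncated
    )


@dataclass(frozen=True)
class EZWidthResult:
    temporal_um: float
    nasal_um: float
    temporal_censored: bool  # no qualifying break before the scan edge
    nasal_censored: bool

    @property
    def total_um(self) -> float:
        return self.temporal_um + self.nasal_um

    @property
    def censored(self) -> bool:
        return self.temporal_censored or self.nasal_censored


def _half_width(
    positions: np.ndarray, intact: np.ndarray, spacing: float, min_break_extent: float
) -> tuple[float, bool]:
    """Distance (µm) from the fovea to the proximal edge of the first
    absence run of lateral extent >= min_break_extent, walking outward
    along one side.  Returns (width, censored)."""
    absent = ~intact
    i = 0
    n = len(positions)
    while i < n:
        if absent[i]:
            j = i
            while j < n and absent[j]:
                j += 1
            extent = (j - i) * spacing
            if extent >= min_break_extent:
                return abs(float(positions[i])), False
        i += 1
    return (abs(float(positions[-1])), True) if n else (0.0, True)


def ez_width(scan: OCTFoveaScan, min_break_extent: float | None = None) -> EZWidthResult:
    """Nasal, temporal and total EZ width.

    On each side of the fovea the width runs to the first EZ absence run
    at least ``min_break_extent`` µm long (default: twice the a-scan
    spacing, so single-sample dropouts are treated as attenuation, not
    loss).  A side with no qualifying break is censored at the scan edge.
    An absent EZ at the fovea itself yields (0, 0, 0).
    """
    spacing = scan.spacing_um
    if min_break_extent is None:
        min_break_extent = 2.0 * spacing
    fi = scan.fovea_index
    if not scan.ez_intact[fi]:
        return EZWidthResult(0.0, 0.0, False, False)
    nasal_pos = scan.lateral_um[fi + 1 :]
    nasal_intact = scan.ez_intact[fi + 1 :]
    temporal_pos = scan.lateral_um[:fi][::-1]
    temporal_intact = scan.ez_intact[:fi][::-1]
    nw, nc = _half_width(nasal_pos, nasal_intact, spacing, min_break_extent)
    tw, tc = _half_width(temporal_pos, temporal_intact, spacing, min_break_extent)
    return EZWidthResult(temporal_um=tw, nasal_um=nw, temporal_censored=tc, nasal_censored=nc)


def foveal_thickness(scan: OCTFoveaScan, kind: str) -> float:
    """Vertical foveal thickness in µm.

    ``CRT``: ILM to posterior RPE-Bruch's boundary; ``PR_RPE``: ELM to the
    same posterior boundary.  A missing boundary returns NaN (a sentinel,
    never a silent zero).
    """
    if kind == "CRT":
        top = scan.ilm_um
    elif kind == "PR_RPE":
        top = scan.elm_um
    else:
        raise ValidationError(f"kind must be 'CRT' or 'PR_RPE', got {kind!r}")
    bottom = scan.rpe_brm_um
    if math.isnan(top) or math.isnan(bottom):
        return math.nan
    return abs(bottom - top)


@dataclass(frozen=True)
class BCVAResult:
    logmar: float
    end_stage: bool  # qualitative code counting-fingers or worse


def bcva_to_logmar(entry) -> BCVAResult:
    """Convert a BCVA record to LogMAR.

    Numeric entries pass through; the qualitative end-stage codes map as
    CF -> 2.6, HM -> 2.7, LP -> 2.8, NLP -> 2.9 LogMAR and are flagged
    ``end_stage`` (excluded from progression modelling downstream).
    """
    if isinstance(entry, str):
        code = entry.strip().upper()
        if code in BCVA_CODES:
            return BCVAResult(BCVA_CODES[code], True)
        try:
            value = float(code)
        except ValueError:
            raise ValidationError(f"unrecognised BCVA entry {entry!r}") from None
        return BCVAResult(value, False)
    value = float(entry)
    if not math.isfinite(value):
        raise ValidationError("BCVA value must be finite")
    return BCVAResult(value, False)


def make_record(
    patient_id: str, eye: str, age_years: float, metric: str, value: float, flags: str = ""
) -> dict:
    """One long-format metric record (patient, eye, age, metric, value)."""
    if metric not in METRIC_UNITS:
        raise ValidationError(f"unknown metric {metric!r}")
    return {
        "patient_id": patient_id,
        "eye": eye,
        "age_years": float(age_years),
        "metric": metric,
        "value": float(value),
        "units": METRIC_UNITS[metric],
        "flags": flags,
    }


def records_frame(records: list[dict]) -> pd.DataFrame:
    cols = ["patient_id", "eye", "age_years", "metric", "value", "units", "flags"]
    return pd.DataFrame(records, columns=cols)
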