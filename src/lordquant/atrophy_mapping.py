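"""Anatomically normalised superpixel atrophy maps.

Eyes differ in fovea-disc distance and in the vertical offset between the
fovea and the optic nerve head (ONH).  To compare atrophy across eyes on
one frame, the nasal half of each (right-eye-format) mask is vertically
sheared so fovea and ONH share a horizontal axis, then a superpixel grid
is built whose cell size is chosen per eye so that exactly 20 superpixels
separate fovea (index ``(0, 0)``) and ONH (index ``(20, 0)``).  Each
superpixel scores the fraction of its pixels that are atrophic; a
superpixel is called atrophic when that fraction is >= 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateAnatomyError, ResolutionError, ShapeMismatchError, ValidationError
from .imaging_io import EyeAnatomy, FAFExam

#: Number of superpixels separating fovea and ONH, by construction.
FOVEA_DISC_SUPERPIXELS = 20

#: Fraction threshold above which a superpixel is called atrophic.
ATROPHY_THRESHOLD = 0.5


def shear_factor(anatomy: EyeAnatomy) -> float:
    """Vertical shear ``s = (y_onh - y_fovea) / (x_onh - x_fovea)`` that
    levels the ONH with the fovea."""
    dx = anatomy.onh_xy[0] - anatomy.fovea_xy[0]
    if dx == 0:
        raise DegenerateAnatomyError("fovea and ONH share the same x; shear undefined")
    return (anatomy.onh_xy[1] - anatomy.fovea_xy[1]) / dx


def shear_align(raster: np.ndarray, anatomy: EyeAnatomy) -> tuple[np.ndarray, float]:
    """Apply the fovea/ONH-levelling vertical shear to the nasal half.

    For pixels with ``x >= x_fovea`` (fovea column inclusive) the forward
    map is ``y' = y - s * (x - x_fovea)``; the temporal half is unchanged
    and horizontal coordinates are never modified.  Resampling is
    nearest-neighbour on the inverse map, so binary masks stay binary and
    integer-shift columns preserve pixel counts.  Returns the sheared
    raster and the shear factor ``s``.
    """
    raster = np.asarray(raster)
    if raster.ndim != 2:
        raise ValidationError("shear_align expects a 2-D raster")
    s = shear_factor(anatomy)
    xf = anatomy.fovea_xy[0]
    h, w = raster.shape
    out = raster.copy()
    cols = np.arange(w)
    nasal = cols[cols >= xf]
    if nasal.size == 0 or s == 0.0:
        return out, s
    yy = np.arange(h)[:, None].astype(float)
    src_y = np.rint(yy + s * (nasal[None, :] - xf)).astype(int)
    valid = (src_y >= 0) & (src_y < h)
    fill = np.zeros((), dtype=raster.dtype)
    block = np.where(valid, raster[src_y.clip(0, h - 1), nasal[None, :]], fill)
    out[:, nasal] = block
    return out, s


def _round_half_away(v: float) -> int:
    return int(math.floor(v + 0.5)) if v >= 0 else -int(math.floor(-v + 0.5))


@dataclass(frozen=True)
class SuperpixelGrid:
    """Per-eye superpixel lattice anchored on the fovea.

    The superpixel size ``n`` (pixels) is chosen so the fovea-ONH
    horizontal distance spans 20 superpixels; superpixel ``(0, 0)`` is
    centred on the fovea, grid x increasing nasally and grid y downward.
    """

    n: int
    fovea_xy: tuple[float, float]
    onh_xy: tuple[float, float]
    shape: tuple[int, int]

    def _index_1d(self, coord: np.ndarray, origin: float) -> np.ndarray:
        return np.floor((np.asarray(coord, dtype=float) - origin) / self.n + 0.5).astype(int)

    def pixel_to_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Grid (gx, gy) of pixel coordinates; fovea superpixel is (0, 0)."""
        return self._index_1d(x, self.fovea_xy[0]), self._index_1d(y, self.fovea_xy[1])

    @property
    def onh_index(self) -> tuple[int, int]:
        gx, gy = self.pixel_to_index(self.onh_xy[0], self.onh_xy[1])
        return int(gx), int(gy)

    @property
    def gx_range(self) -> tuple[int, int]:
        h, w = self.shape
        lo, hi = self.pixel_to_index(np.array([0, w - 1]), np.array([0, 0]))[0][[0, 1]]
        return int(lo), int(hi)

    @property
    def gy_range(self) -> tuple[int, int]:
        h, w = self.shape
        idx = self._index_1d(np.array([0, h - 1]), self.fovea_xy[1])
        return int(idx[0]), int(idx[1])


def build_grid(anatomy: EyeAnatomy, shape: tuple[int, int]) -> SuperpixelGrid:
    """Build the 20-superpixel fovea-disc grid for a sheared, right-eye
    format frame (fovea and ONH level, ONH nasal of the fovea).

    ``n = round(|x_onh - x_fovea| / 20)`` (half away from zero); the ONH
    centre then lands in superpixel column 20 for any anatomy with a
    fovea-disc distance of at least 20 px.
    """
    dx = anatomy.onh_xy[0] - anatomy.fovea_xy[0]
    if dx <= 0:
        raise DegenerateAnatomyError(
            "grid requires right-eye format with the ONH nasal (x_onh > x_fovea)"
        )
    if dx < FOVEA_DISC_SUPERPIXELS:
        raise ResolutionError(
            f"fovea-disc distance {dx:.1f} px < {FOVEA_DISC_SUPERPIXELS} px; grid unresolvable"
        )
    n = max(1, _round_half_away(dx / FOVEA_DISC_SUPERPIXELS))
    # the sheared frame levels the ONH with the fovea by construction
    return SuperpixelGrid(
        n=n,
        fovea_xy=anatomy.fovea_xy,
        onh_xy=(anatomy.onh_xy[0], anatomy.fovea_xy[1]),
        shape=tuple(shape),
    )


@dataclass
class AtrophyMap:
    """Superpixel map of atrophic fractions for one exam.

    ``fractions[gy - gy_min, gx - gx_min]`` is the proportion of atrophic
    (non-peripapillary) pixels in that superpixel; ``pixel_counts`` holds
    the in-frame pixel denominator (``n**2`` for interior superpixels,
    fewer at clipped edges).
    """

    fractions: np.ndarray
    pixel_counts: np.ndarray
    gx_min: int
    gy_min: int
    n: int
    theta: float = ATROPHY_THRESHOLD
    exam_id: str = ""
    shear: float = 0.0
    age_years: float | None = None
    patient_id: str = ""
    eye: str = ""

    @property
    def binarized(self) -> np.ndarray:
        """Boolean layer: superpixel atrophic when fraction >= theta."""
        return self.fractions >= self.theta

    @property
    def gx_values(self) -> np.ndarray:
        return self.gx_min + np.arange(self.fractions.shape[1])

    @property
    def gy_values(self) -> np.ndarray:
        return self.gy_min + np.arange(self.fractions.shape[0])

    def fraction_at(self, gx: int, gy: int) -> float:
        return float(self.fractions[gy - self.gy_min, gx - self.gx_min])

    def to_frame(self) -> pd.DataFrame:
        gy, gx = np.meshgrid(self.gy_values, self.gx_values, indexing="ij")
        return pd.DataFrame(
            {
                "exam_id": self.exam_id,
                "gx": gx.ravel(),
                "gy": gy.ravel(),
                "fraction": self.fractions.ravel(),
                "atrophic_flag": self.binarized.ravel().astype(int),
            }
        )


def compute_atrophy_map(
    atrophy_mask: np.ndarray,
    peripapillary_mask: np.ndarray | None,
    grid: SuperpixelGrid,
    theta: float = ATROPHY_THRESHOLD,
    **provenance,
) -> AtrophyMap:
    """Score atrophic fractions per superpixel in the sheared frame.

    Peripapillary pixels are excluded from the numerator (peripapillary
    atrophy does not count as disease atrophy); clipped edge superpixels
    are scored over their in-frame pixels only.
    """
    atrophy_mask = np.asarray(atrophy_mask).astype(bool)
    if atrophy_mask.shape != grid.shape:
        raise ShapeMismatchError(
            f"mask shape {atrophy_mask.shape} does not match grid frame {grid.shape}"
        )
    if peripapillary_mask is None:
        effective = atrophy_mask
    else:
        peripapillary_mask = np.asarray(peripapillary_mask).astype(bool)
        if peripapillary_mask.shape != grid.shape:
            raise ShapeMismatchError("peripapillary mask shape does not match grid frame")
        effective = atrophy_mask & ~peripapillary_mask
    h, w = grid.shape
    cx, _ = grid.pixel_to_index(np.arange(w), np.zeros(w))
    _, ry = grid.pixel_to_index(np.zeros(h), np.arange(h))
    gx_min, gx_max = int(cx.min()), int(cx.max())
    gy_min, gy_max = int(ry.min()), int(ry.max())
    ngx, ngy = gx_max - gx_min + 1, gy_max - gy_min + 1
    label = (ry - gy_min)[:, None] * ngx + (cx - gx_min)[None, :]
    denom = np.bincount(label.ravel(), minlength=ngx * ngy).reshape(ngy, ngx)
    num = np.bincount(
        label.ravel(), weights=effective.ravel().astype(float), minlength=ngx * ngy
    ).reshape(ngy, ngx)
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = np.where(denom > 0, num / np.maximum(denom, 1), 0.0)
    return AtrophyMap(
        fractions=fractions,
        pixel_counts=denom,
        gx_min=gx_min,
        gy_min=gy_min,
        n=grid.n,
        theta=theta,
        **provenance,
    )


def map_exam(exam: FAFExam, theta: float = ATROPHY_THRESHOLD) -> AtrophyMap:
    """Convenience: shear-align an exam's masks and score the superpixel
    map in one step (exam must be in right-eye format)."""
    sheared_atrophy, s = shear_align(exam.atrophy_mask, exam.anatomy)
    sheared_peri, _ = shear_align(exam.peripapillary_mask, exam.anatomy)
    grid = build_grid(exam.anatomy, exam.shape)
    return compute_atrophy_map(
        sheared_atrophy,
        sheared_peri,
        grid,
        theta=theta,
        exam_id=exam.exam_id,
        shear=s,
        age_years=exam.age_at_exam,
        patient_id=exam.patient_id,
        eye=exam.eye,
    )
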