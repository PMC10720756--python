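"""Projective registration of follow-up exams to baseline.

Follow-up FAF images are aligned to the baseline visit from manually (or
synthetically) identified corresponding control points.  At least nine
point pairs marking the same retinal detail are required by default; the
projective (homography) transform is estimated by the conditioning-
normalised direct linear transform, which is exact for noise-free points
and least-squares otherwise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import ProjectiveTransform, warp

from .errors import DegenerateControlPointsError, InsufficientPointsError, ValidationError

DEFAULT_MIN_POINTS = 9


@dataclass(frozen=True)
class ControlPointSet:
    """Paired pixel coordinates linking a follow-up exam to its baseline.

    ``base`` and ``follow`` are (n, 2) arrays of (x, y) coordinates.
    """

    base: np.ndarray
    follow: np.ndarray

    def __post_init__(self) -> None:
        base = np.atleast_2d(np.asarray(self.base, dtype=float))
        follow = np.atleast_2d(np.asarray(self.follow, dtype=float))
        if base.shape != follow.shape or base.shape[1] != 2:
            raise ValidationError("base and follow must both be (n, 2) arrays")
        if not (np.isfinite(base).all() and np.isfinite(follow).all()):
            raise ValidationError("control points must be finite")
        object.__setattr__(self, "base", base)
        object.__setattr__(self, "follow", follow)

    @property
    def n(self) -> int:
        return self.base.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_base": self.base[:, 0],
                "y_base": self.base[:, 1],
                "x_follow": self.follow[:, 0],
                "y_follow": self.follow[:, 1],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ControlPointSet":
        df = pd.read_csv(path)
        return cls(
            base=df[["x_base", "y_base"]].to_numpy(),
            follow=df[["x_follow", "y_follow"]].to_numpy(),
        )


@dataclass(frozen=True)
class Homography:
    """3x3 projective matrix mapping follow-up coordinates onto baseline,
    normalised so the bottom-right entry equals 1."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3) or not np.isfinite(m).all():
            raise ValidationError("homography must be a finite 3x3 matrix")
        if abs(m[2, 2]) < 1e-12 or abs(np.linalg.det(m)) < 1e-12:
            raise ValidationError("homography is singular or unnormalisable")
        object.__setattr__(self, "matrix", m / m[2, 2])

    @classmethod
    def identity(cls) -> "Homography":
        return cls(np.eye(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 2) points through the homography."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        homo = np.column_stack([pts, np.ones(len(pts))]) @ self.matrix.T
        return homo[:, :2] / homo[:, 2:3]

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix))

    def compose(self, other: "Homography") -> "Homography":
        """Return self ∘ other (apply ``other`` first)."""
        return Homography(self.matrix @ other.matrix)

    def to_row(self) -> np.ndarray:
        return self.matrix.ravel()

    @classmethod
    def from_row(cls, row) -> "Homography":
        return cls(np.asarray(row, dtype=float).reshape(3, 3))


def _check_nondegenerate(pts: np.ndarray) -> None:
    if len(np.unique(pts.round(9), axis=0)) < len(pts):
        raise DegenerateControlPointsError("duplicate control points")
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8 * max(1.0, np.abs(pts).max())) < 2:
        raise DegenerateControlPointsError("control points are collinear")


def estimate_projective(points: ControlPointSet, min_points: int = DEFAULT_MIN_POINTS) -> Homography:
    """Estimate the homography mapping follow-up points onto baseline.

    Uses the normalised (Hartley-conditioned) direct linear transform via
    scikit-image; exact when points are noise-free, least-squares under
    jitter.  Raises :class:`InsufficientPointsError` below ``min_points``
    (pipeline default 9) and :class:`DegenerateControlPointsError` for
    duplicate or collinear configurations.
    """
    if points.n < min_points:
        raise InsufficientPointsError(
            f"{points.n} control points provided; at least {min_points} required"
        )
    _check_nondegenerate(points.base)
    _check_nondegenerate(points.follow)
    tform = ProjectiveTransform.from_estimate(src=points.follow, dst=points.base)
    if not tform or not np.isfinite(tform.params).all():
        raise DegenerateControlPointsError("homography estimation failed (rank deficient)")
    return Homography(tform.params)


def apply_transform(raster: np.ndarray, h: Homography, kind: str = "image") -> np.ndarray:
    """Warp a follow-up raster onto the baseline grid.

    Masks are resampled nearest-neighbour (stay binary); images bilinear.
    Out-of-frame pixels are filled with 0 / background.
    """
    if kind not in ("image", "mask"):
        raise ValidationError(f"kind must be 'image' or 'mask', got {kind!r}")
    # warp() maps output (baseline) coords through the given transform to
    # input (follow-up) coords, i.e. it needs H^{-1}.
    tform = ProjectiveTransform(matrix=h.inverse().matrix)
    order = 0 if kind == "mask" else 1
    arr = raster.astype(float) if kind == "mask" else raster
    out = warp(arr, tform, order=order, cval=0.0, preserve_range=True)
    if kind == "mask":
        return out > 0.5
    return out.astype(raster.dtype) if raster.dtype.kind in "ui" else out


def register_exam(exam, points: ControlPointSet, min_points: int = DEFAULT_MIN_POINTS):
    """Register a follow-up exam to baseline: estimate H and warp image and
    masks onto the baseline grid.  Returns ``(registered_exam, H)``."""
    h = estimate_projective(points, min_points=min_points)
    return (
        dataclasses.replace(
            exam,
            image=apply_transform(exam.image, h, kind="image"),
            atrophy_mask=apply_transform(exam.atrophy_mask, h, kind="mask"),
            peripapillary_mask=apply_transform(exam.peripapillary_mask, h, kind="mask"),
        ),
        h,
    )


def reprojection_error(points: ControlPointSet, h: Homography) -> float:
    """Root-mean-square distance (px) between H-mapped follow-up points and
    their baseline counterparts; quality control for the manual step."""
    mapped = h.apply(points.follow)
    return float(np.sqrt(np.mean(np.sum((mapped - points.base) ** 2, axis=1))))
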