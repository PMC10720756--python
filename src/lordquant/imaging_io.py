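"""Exam containers, file I/O, and the right-eye coordinate convention.

A fundus-autofluorescence (FAF) exam is a grayscale raster plus binary
atrophy / peripapillary masks and the anatomical landmarks (fovea and
optic nerve head) that anchor all downstream geometry.  Coordinates are
0-based pixel-center, ``x`` increasing rightward (columns) and ``y``
downward (rows).  In right-eye format the optic nerve head (ONH) lies
nasal of the fovea, i.e. at larger ``x``; left eyes are mirrored about
the vertical image midline to reach that format.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import ShapeMismatchError, SidecarError, ValidationError

RIGHT = "right"
LEFT = "left"

#: Sidecar keys that must be present for an exam to load.
SIDECAR_KEYS = (
    "patient_id",
    "eye",
    "age_years",
    "pixel_scale_um_per_px",
    "fovea_xy",
    "onh_xy",
    "laterality",
)


@dataclass(frozen=True)
class EyeAnatomy:
    """Landmark geometry of one eye.

    Parameters
    ----------
    fovea_xy, onh_xy : tuple of float
        Pixel coordinates (x, y) of the fovea and optic nerve head.
    pixel_scale : float
        Lateral resolution in micrometres per pixel.
    laterality : {"right", "left"}
        Anatomical side of the eye in the *current* raster orientation.
    """

    fovea_xy: tuple[float, float]
    onh_xy: tuple[float, float]
    pixel_scale: float
    laterality: str = RIGHT

    def __post_init__(self) -> None:
        if self.pixel_scale <= 0 or not np.isfinite(self.pixel_scale):
            raise ValidationError(f"pixel_scale must be > 0, got {self.pixel_scale}")
        if tuple(self.fovea_xy) == tuple(self.onh_xy):
            raise ValidationError("fovea and ONH coincide")
        if self.laterality not in (RIGHT, LEFT):
            raise ValidationError(f"laterality must be 'right' or 'left', got {self.laterality!r}")
        object.__setattr__(self, "fovea_xy", (float(self.fovea_xy[0]), float(self.fovea_xy[1])))
        object.__setattr__(self, "onh_xy", (float(self.onh_xy[0]), float(self.onh_xy[1])))

    @property
    def fovea_disc_px(self) -> float:
        """Euclidean fovea-ONH distance in pixels."""
        return float(np.hypot(self.onh_xy[0] - self.fovea_xy[0], self.onh_xy[1] - self.fovea_xy[1]))

    @property
    def fovea_disc_um(self) -> float:
        return self.fovea_disc_px * self.pixel_scale


@dataclass
class FAFExam:
    """One FAF examination: raster, masks, anatomy and identity."""

    image: np.ndarray
    atrophy_mask: np.ndarray
    peripapillary_mask: np.ndarray
    anatomy: EyeAnatomy
    patient_id: str
    eye: str
    age_at_exam: float
    field_of_view: str = "55"
    original_laterality: str | None = None
    exam_id: str = field(default="")

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        self.atrophy_mask = np.asarray(self.atrophy_mask).astype(bool)
        if self.peripapillary_mask is None:
            self.peripapillary_mask = np.zeros(self.image.shape, dtype=bool)
        self.peripapillary_mask = np.asarray(self.peripapillary_mask).astype(bool)
        if self.image.ndim != 2:
            raise ValidationError("exam image must be a 2-D grayscale raster")
        for name, m in (("atrophy_mask", self.atrophy_mask), ("peripapillary_mask", self.peripapillary_mask)):
            if m.shape != self.image.shape:
                raise ShapeMismatchError(
                    f"{name} shape {m.shape} differs from image shape {self.image.shape}"
                )
        h, w = self.image.shape
        for label, (x, y) in (("fovea", self.anatomy.fovea_xy), ("onh", self.anatomy.onh_xy)):
            if not (0 <= x < w and 0 <= y < h):
                raise ValidationError(f"{label} coordinates {(x, y)} fall outside the raster")
        if not self.exam_id:
            self.exam_id = f"{self.patient_id}_{self.eye}_{self.age_at_exam:.2f}"

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape


def _read_raster(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path))
    import imageio.v3 as iio

    return np.asarray(iio.imread(path))


def load_exam(
    image_path: str | Path,
    atrophy_mask_path: str | Path,
    sidecar: str | Path | dict,
    peripapillary_mask_path: str | Path | None = None,
) -> FAFExam:
    """Load an exam triplet (image, masks, JSON sidecar) and validate it.

    The sidecar is either a JSON file path or an already-parsed dict with
    keys ``patient_id, eye, age_years, pixel_scale_um_per_px, fovea_xy,
    onh_xy, laterality`` (``field_of_view`` optional).
    """
    if not isinstance(sidecar, dict):
        with open(sidecar) as fh:
            sidecar = json.load(fh)
    missing = [k for k in SIDECAR_KEYS if k not in sidecar]
    if missing:
        raise SidecarError(f"sidecar missing keys: {missing}")
    image = _read_raster(image_path)
    atrophy = _read_raster(atrophy_mask_path) > 0
    peri = None
    if peripapillary_mask_path is not None:
        peri = _read_raster(peripapillary_mask_path) > 0
    anatomy = EyeAnatomy(
        fovea_xy=tuple(sidecar["fovea_xy"]),
        onh_xy=tuple(sidecar["onh_xy"]),
        pixel_scale=float(sidecar["pixel_scale_um_per_px"]),
        laterality=str(sidecar["laterality"]),
    )
    return FAFExam(
        image=image,
        atrophy_mask=atrophy,
        peripapillary_mask=peri,
        anatomy=anatomy,
        patient_id=str(sidecar["patient_id"]),
        eye=str(sidecar["eye"]),
        age_at_exam=float(sidecar["age_years"]),
        field_of_view=str(sidecar.get("field_of_view", "55")),
    )


def save_exam(exam: FAFExam, directory: str | Path, stem: str | None = None) -> dict[str, Path]:
    """Write an exam as TIFF rasters plus a JSON sidecar; return the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or exam.exam_id
    paths = {
        "image": directory / f"{stem}_faf.tiff",
        "atrophy": directory / f"{stem}_atrophy.tiff",
        "peripapillary": directory / f"{stem}_peripapillary.tiff",
        "sidecar": directory / f"{stem}_meta.json",
    }
    img = exam.image
    if img.dtype.kind == "f":
        img = np.clip(img * 255.0, 0, 255).astype(np.uint8)
    tifffile.imwrite(paths["image"], img)
    tifffile.imwrite(paths["atrophy"], exam.atrophy_mask.astype(np.uint8) * 255)
    tifffile.imwrite(paths["peripapillary"], exam.peripapillary_mask.astype(np.uint8) * 255)
    meta = {
        "patient_id": exam.patient_id,
        "eye": exam.eye,
        "age_years": exam.age_at_exam,
        "pixel_scale_um_per_px": exam.anatomy.pixel_scale,
        "fovea_xy": list(exam.anatomy.fovea_xy),
        "onh_xy": list(exam.anatomy.onh_xy),
        "laterality": exam.anatomy.laterality,
        "field_of_view": exam.field_of_view,
    }
    with open(paths["sidecar"], "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return paths


def mirror_x(xy: tuple[float, float], width: int) -> tuple[float, float]:
    """Mirror a pixel-center coordinate about the vertical image midline."""
    return (width - 1 - xy[0], xy[1])


def flip_to_right_eye(exam: FAFExam) -> FAFExam:
    """Mirror a left eye into right-eye format; right eyes pass through.

    The image, both masks and both landmark coordinates are mirrored about
    the vertical midline so the ONH ends up nasal (x > fovea x).  The
    original laterality is recorded on the returned exam.  The operation
    is an involution on coordinates (flipping twice restores them).
    """
    if exam.anatomy.laterality == RIGHT:
        if exam.original_laterality is None:
            exam = dataclasses.replace(exam, original_laterality=RIGHT)
        return exam
    w = exam.shape[1]
    anatomy = EyeAnatomy(
        fovea_xy=mirror_x(exam.anatomy.fovea_xy, w),
        onh_xy=mirror_x(exam.anatomy.onh_xy, w),
        pixel_scale=exam.anatomy.pixel_scale,
        laterality=RIGHT,
    )
    return dataclasses.replace(
        exam,
        image=exam.image[:, ::-1].copy(),
        atrophy_mask=exam.atrophy_mask[:, ::-1].copy(),
        peripapillary_mask=exam.peripapillary_mask[:, ::-1].copy(),
        anatomy=anatomy,
        original_laterality=exam.original_laterality or LEFT,
    )
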