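"""Age-stratified spatial prevalence of atrophy on the common grid.

Because every eye's superpixel map shares the same anatomical frame
(fovea at (0, 0), ONH at (20, 0)), maps from different eyes and visits
can be pooled.  Exams are stratified by age at examination (5-year
strata from age 55) and, per superpixel location, the percentage of
exams showing atrophy (binarized layer) is computed.  Locations observed
in fewer than ``min_exams`` exams are censored.  Multiple exams per eye
may fall in one stratum; narrow-field exams simply contribute no
observation at peripheral locations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .atrophy_mapping import AtrophyMap
from .errors import ValidationError

DEFAULT_BREAKS = (55.0, 60.0, 65.0, 70.0)
MIN_EXAMS = 4


@dataclass
class AgeStratumMap:
    """Per-stratum spatial prevalence of atrophy.

    ``percent`` is NaN where censored (fewer than ``min_exams`` exams).
    """

    label: str
    n_exams: np.ndarray
    n_atrophic: np.ndarray
    gx_min: int
    gy_min: int
    min_exams: int = MIN_EXAMS

    @property
    def censored(self) -> np.ndarray:
        return self.n_exams < self.min_exams

    @property
    def percent(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.n_atrophic / self.n_exams
        return np.where(self.censored, np.nan, pct)

    @property
    def gx_values(self) -> np.ndarray:
        return self.gx_min + np.arange(self.n_exams.shape[1])

    @property
    def gy_values(self) -> np.ndarray:
        return self.gy_min + np.arange(self.n_exams.shape[0])

    def to_frame(self) -> pd.DataFrame:
        gy, gx = np.meshgrid(self.gy_values, self.gx_values, indexing="ij")
        return pd.DataFrame(
            {
                "stratum": self.label,
                "gx": gx.ravel(),
                "gy": gy.ravel(),
                "n_exams": self.n_exams.ravel(),
                "percent": self.percent.ravel(),
                "censored": self.censored.ravel().astype(int),
            }
        )


def stratum_labels(breaks) -> list[str]:
    labels = [f"<={breaks[0]:g}"]
    labels += [f"{a:g}-{b:g}" for a, b in zip(breaks[:-1], breaks[1:])]
    labels.append(f">{breaks[-1]:g}")
    return labels


def assign_stratum(age: float, breaks) -> str:
    """Half-open, upper-inclusive strata: (-inf, b0], (b0, b1], ..., (bk, inf)."""
    labels = stratum_labels(breaks)
    idx = int(np.searchsorted(np.asarray(breaks, dtype=float), age, side="left"))
    if idx < len(breaks) and age == breaks[idx]:
        return labels[idx]
    return labels[idx]


def _common_extents(maps: list[AtrophyMap], crop: bool) -> tuple[int, int, int, int]:
    gx_lo = max(m.gx_min for m in maps)
    gx_hi = min(m.gx_min + m.fractions.shape[1] - 1 for m in maps)
    gy_lo = max(m.gy_min for m in maps)
    gy_hi = min(m.gy_min + m.fractions.shape[0] - 1 for m in maps)
    full = all(
        m.gx_min == gx_lo
        and m.gy_min == gy_lo
        and m.fractions.shape == (gy_hi - gy_lo + 1, gx_hi - gx_lo + 1)
        for m in maps
    )
    if not full:
        if not crop:
            raise ValidationError("atrophy maps have inconsistent grid extents")
        warnings.warn("atrophy maps cropped to their common grid intersection", stacklevel=3)
    if gx_hi < gx_lo or gy_hi < gy_lo:
        raise ValidationError("atrophy maps share no common grid region")
    return gx_lo, gx_hi, gy_lo, gy_hi


def stratify_and_prevalence(
    maps: list[AtrophyMap],
    ages: list[float] | None = None,
    breaks=DEFAULT_BREAKS,
    min_exams: int = MIN_EXAMS,
    crop_to_common: bool = True,
) -> dict[str, AgeStratumMap]:
    """Pool binarized maps into per-age-stratum prevalence maps.

    ``ages`` defaults to each map's recorded ``age_years``.  Per location,
    an exam contributes an observation only where its map actually covers
    that superpixel (``pixel_counts > 0``), so narrow-field exams are
    counted only over their imaged field.
    """
    if not maps:
        raise ValidationError("no atrophy maps supplied")
    if ages is None:
        ages = [m.age_years for m in maps]
        if any(a is None for a in ages):
            raise ValidationError("maps lack ages; pass the ages argument")
    if len(ages) != len(maps):
        raise ValidationError("ages and maps length mismatch")
    gx_lo, gx_hi, gy_lo, gy_hi = _common_extents(maps, crop_to_common)
    shape = (gy_hi - gy_lo + 1, gx_hi - gx_lo + 1)
    labels = stratum_labels(breaks)
    strata = {
        lab: AgeStratumMap(
            label=lab,
            n_exams=np.zeros(shape, dtype=int),
            n_atrophic=np.zeros(shape, dtype=int),
            gx_min=gx_lo,
            gy_min=gy_lo,
            min_exams=min_exams,
        )
        for lab in labels
    }
    for m, age in zip(maps, ages):
        lab = assign_stratum(float(age), breaks)
        ys = slice(gy_lo - m.gy_min, gy_hi - m.gy_min + 1)
        xs = slice(gx_lo - m.gx_min, gx_hi - m.gx_min + 1)
        observed = m.pixel_counts[ys, xs] > 0
        strata[lab].n_exams += observed.astype(int)
        strata[lab].n_atrophic += (m.binarized[ys, xs] & observed).astype(int)
    return strata


def export_heatmaps(
    strata: dict[str, AgeStratumMap],
    csv_path: str | Path,
    png_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Write the long-format prevalence table (and optional PNG heatmaps
    with a fovea marker); returns the table."""
    frames = [s.to_frame() for s in strata.values()]
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(csv_path, index=False)
    if png_dir is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        png_dir = Path(png_dir)
        png_dir.mkdir(parents=True, exist_ok=True)
        for lab, s in strata.items():
            fig, ax = plt.subplots(figsize=(6, 5))
            extent = [
                s.gx_values[0] - 0.5,
                s.gx_values[-1] + 0.5,
                s.gy_values[-1] + 0.5,
                s.gy_values[0] - 0.5,
            ]
            im = ax.imshow(s.percent, extent=extent, cmap="inferno", vmin=0, vmax=100)
            ax.plot(0, 0, "c+", markersize=12, label="fovea")
            ax.set_title(f"atrophy prevalence, age {lab} y")
            ax.set_xlabel("superpixels (nasal →)")
            ax.set_ylabel("superpixels")
            fig.colorbar(im, ax=ax, label="% of exams atrophic")
            safe = lab.replace("<=", "le").replace(">", "gt").replace("-", "_")
            fig.savefig(png_dir / f"prevalence_{safe}.png", dpi=120)
            plt.close(fig)
    return table
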