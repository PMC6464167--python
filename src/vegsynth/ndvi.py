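"""NDVI compositing and zonal statistics.

Builds the outcome panel from reflectance rasters: per-pixel normalized
difference vegetation index ``NDVI = (NIR - Red) / (NIR + Red)``, bounded
in [-1, +1]; cloud-aware greenest-pixel seasonal composites (per-pixel
maximum NDVI across same-season scenes, so cloud-masked pixels are filled
from clearer acquisitions); and per-unit mean annual NDVI, averaging the
five-season composites (winter, spring, summer, monsoon, autumn) equally.

Scene admission (cloud-cover screening, gap filling of striped sensors) is
the caller's responsibility; per-pixel validity travels with each scene as
a boolean mask. Rasters are row-major, origin top-left; no reprojection is
performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import PanelValidationError

__all__ = [
    "SEASONS",
    "RasterScene",
    "UnitMask",
    "ndvi",
    "greenest_pixel_composite",
    "annual_unit_means",
    "unit_means_to_long_frame",
    "read_scene_csv",
    "read_scene_tiff",
]

SEASONS = ("winter", "spring", "summer", "monsoon", "autumn")


@dataclass(frozen=True)
class RasterScene:
    """One acquisition: NIR and red reflectance plus a validity mask.

    ``valid_mask`` is ``False`` where the pixel is cloud-contaminated or
    missing. Reflectances must lie in [0, 1] wherever valid.
    """

    nir: np.ndarray
    red: np.ndarray
    valid_mask: np.ndarray
    date: str = ""
    season: str = ""

    def __post_init__(self) -> None:
        nir = np.asarray(self.nir, dtype=float)
        red = np.asarray(self.red, dtype=float)
        mask = np.asarray(self.valid_mask, dtype=bool)
        object.__setattr__(self, "nir", nir)
        object.__setattr__(self, "red", red)
        object.__setattr__(self, "valid_mask", mask)
        if not (nir.shape == red.shape == mask.shape) or nir.ndim != 2:
            raise PanelValidationError("nir/red/valid_mask must share a 2-D shape")
        if self.season and self.season not in SEASONS:
            raise PanelValidationError(
                f"season {self.season!r} not one of {SEASONS}"
            )
        for name, band in (("nir", nir), ("red", red)):
            vals = band[mask]
            if len(vals) and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
                raise PanelValidationError(
                    f"{name} reflectance outside [0, 1] at valid pixels"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.nir.shape


@dataclass(frozen=True)
class UnitMask:
    """Integer raster mapping each pixel to a unit id; 0 is background."""

    labels: np.ndarray
    unit_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2 or not np.issubdtype(labels.dtype, np.integer):
            raise PanelValidationError("unit mask must be a 2-D integer array")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "unit_ids", tuple(self.unit_ids))
        present = set(np.unique(labels)) - {0}
        if present - set(range(1, len(self.unit_ids) + 1)):
            raise PanelValidationError("mask labels exceed the unit list")
        for i in range(1, len(self.unit_ids) + 1):
            if i not in present:
                raise PanelValidationError(
                    f"unit {self.unit_ids[i - 1]!r} has no pixels in the mask"
                )


def ndvi(scene: RasterScene) -> np.ma.MaskedArray:
    """Per-pixel NDVI of a scene, masked where invalid.

    A valid pixel with ``nir + red == 0`` has an undefined index; it is
    flagged missing with a warning rather than raising.
    """
    total = scene.nir + scene.red
    degenerate = scene.valid_mask & (total == 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} valid pixel(s) with nir + red == 0; "
            "flagged missing",
            stacklevel=2,
        )
    usable = scene.valid_mask & ~degenerate
    out = np.zeros(scene.shape, dtype=float)
    np.divide(scene.nir - scene.red, total, out=out, where=usable)
    return np.ma.MaskedArray(out, mask=~usable)


def greenest_pixel_composite(scenes) -> np.ma.MaskedArray:
    """Greenest-pixel (maximum-NDVI) mosaic over same-season scenes.

    Per pixel, the maximum NDVI across scenes where that scene's validity
    mask is true; a pixel is missing only if invalid in every scene.
    """
    scenes = list(scenes)
    if not scenes:
        raise PanelValidationError("need at least one scene to composite")
    shape = scenes[0].shape
    if any(s.shape != shape for s in scenes):
        raise PanelValidationError("scene shapes disagree")
    seasons = {s.season for s in scenes if s.season}
    if len(seasons) > 1:
        raise PanelValidationError(
            f"compositing mixes seasons {sorted(seasons)}; composite one season"
        )
    stack = np.ma.stack([ndvi(s) for s in scenes])
    return stack.max(axis=0)


def annual_unit_means(
    seasonal_composites: dict, mask: UnitMask
) -> pd.Series:
    """Mean annual NDVI per unit from one year's seasonal composites.

    For each unit: the mean over valid unit pixels within each available
    seasonal composite, then the equal-weight mean over seasons (seasons
    with no valid pixels for a unit are skipped). Units with no valid
    pixels in any season are reported missing (NaN).

    ``seasonal_composites`` maps season label to a masked NDVI array; all
    five seasons are expected, fewer are allowed with a warning.
    """
    missing_seasons = [s for s in SEASONS if s not in seasonal_composites]
    unknown = set(seasonal_composites) - set(SEASONS)
    if unknown:
        raise PanelValidationError(f"unknown season labels: {sorted(unknown)}")
    if missing_seasons:
        warnings.warn(
            f"missing seasonal composites: {missing_seasons}; averaging the rest",
            stacklevel=2,
        )
    shape = mask.labels.shape
    for season, comp in seasonal_composites.items():
        if comp.shape != shape:
            raise PanelValidationError(
                f"{season} composite shape {comp.shape} != mask shape {shape}"
            )
    means = {}
    for i, unit in enumerate(mask.unit_ids, start=1):
        in_unit = mask.labels == i
        seasonal = []
        for season in SEASONS:
            if season not in seasonal_composites:
                continue
            comp = np.ma.asarray(seasonal_composites[season])
            vals = comp[in_unit]
            if vals.count():
                seasonal.append(float(vals.mean()))
        means[unit] = float(np.mean(seasonal)) if seasonal else np.nan
    return pd.Series(means, name="mean_annual_ndvi")


def unit_means_to_long_frame(means_by_year: dict) -> pd.DataFrame:
    """Assemble per-year unit means into the long outcome-panel format
    (columns ``unit, year, value``) used by :mod:`vegsynth.panel`."""
    rows = []
    for year in sorted(means_by_year):
        series = means_by_year[year]
        for unit, value in series.items():
            rows.append({"unit": unit, "year": int(year), "value": value})
    return pd.DataFrame(rows, columns=["unit", "year", "value"])


def read_scene_csv(
    nir_path: str | Path,
    red_path: str | Path,
    mask_path: str | Path | None = None,
    **meta,
) -> RasterScene:
    """Read a scene from plain CSV grids (one row per raster row)."""
    nir = np.loadtxt(nir_path, delimiter=",", ndmin=2)
    red = np.loadtxt(red_path, delimiter=",", ndmin=2)
    if mask_path is not None:
        mask = np.loadtxt(mask_path, delimiter=",", ndmin=2) > 0
    else:
        mask = np.ones_like(nir, dtype=bool)
    return RasterScene(nir=nir, red=red, valid_mask=mask, **meta)


def read_scene_tiff(path: str | Path, **meta) -> RasterScene:
    """Read a multi-band TIFF raster (band order: NIR, red, optional
    validity mask; mask defaults to all-valid)."""
    import tifffile

    arr = np.asarray(tifffile.imread(path), dtype=float)
    if arr.ndim == 3 and arr.shape[0] not in (2, 3) and arr.shape[-1] in (2, 3):
        arr = np.moveaxis(arr, -1, 0)  # accept band-last layouts
    if arr.ndim != 3 or arr.shape[0] not in (2, 3):
        raise PanelValidationError(
            f"expected a 2- or 3-band raster in {path}, got shape {arr.shape}"
        )
    nir, red = arr[0], arr[1]
    mask = arr[2] > 0 if arr.shape[0] == 3 else np.ones_like(nir, dtype=bool)
    return RasterScene(nir=nir, red=red, valid_mask=mask, **meta)
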