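"""Vegetation-greenness composites and climate-anomaly standardization.

NDVI = (NIR - RED) / (NIR + RED) per cloud-free cell; per-season rasters are
pixel-wise maximum composites over the scenes falling in the seasonal
window (February-April for the peak dry season, September-November for the
peak wet season).  Water-balance anomalies (SPEI) are consumed as a
season-labelled series and standardized within season so that zero means
"typical for that season" and the units are season-specific standard
deviations.
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd
import shapely

from .grids import Raster

if TYPE_CHECKING:  # pragma: no cover
    from shapely.geometry.base import BaseGeometry

__all__ = [
    "compute_ndvi",
    "max_composite",
    "seasonal_composite",
    "standardize_spei",
    "mean_raster_in_range",
    "SEASON_WINDOWS",
]

#: Month windows of the peak-season composites (inclusive).
SEASON_WINDOWS = {"dry": (2, 4), "wet": (9, 11)}


def compute_ndvi(red: Raster, nir: Raster, qa: Raster | np.ndarray | None = None) -> Raster:
    """Per-cell NDVI; QA-flagged or zero-reflectance cells become missing.

    ``qa`` is a boolean layer (True = contaminated).  Reflectances must be
    non-negative; missing reflectance propagates to missing NDVI.
    """
    if not red.same_geometry(nir):
        raise ValueError("red and nir rasters must share identical geometry")
    r, n = red.values, nir.values
    if np.nanmin(r) < 0 or np.nanmin(n) < 0:
        raise ValueError("reflectances must be non-negative")
    denom = n + r
    with np.errstate(invalid="ignore", divide="ignore"):
        ndvi = np.where(denom > 0, (n - r) / denom, np.nan)
    ndvi = np.where(np.isnan(r) | np.isnan(n), np.nan, ndvi)
    if qa is not None:
        qmask = qa.values.astype(bool) if isinstance(qa, Raster) else np.asarray(qa, bool)
        if isinstance(qa, Raster) and not qa.same_geometry(red):
            raise ValueError("qa raster must share geometry with reflectance rasters")
        if qmask.shape != red.grid.shape:
            raise ValueError("qa mask shape does not match grid")
        ndvi = np.where(qmask, np.nan, ndvi)
    return Raster(red.grid, ndvi)


def max_composite(rasters: Iterable[Raster]) -> Raster:
    """Pixel-wise maximum over non-missing values; all-missing stays missing."""
    rasters = list(rasters)
    if not rasters:
        raise ValueError("max_composite needs at least one raster")
    grid = rasters[0].grid
    for r in rasters[1:]:
        if r.grid != grid:
            raise ValueError("all rasters must share identical geometry")
    stack = np.stack([r.values for r in rasters])
    all_missing = np.all(np.isnan(stack), axis=0)
    filled = np.where(np.isnan(stack), -np.inf, stack)
    out = filled.max(axis=0)
    out[all_missing] = np.nan
    return Raster(grid, out)


def seasonal_composite(scenes, year: int, season: str) -> Raster:
    """Maximum NDVI composite over scenes in the year's seasonal window.

    ``scenes`` is an iterable of objects with ``date`` (anything with
    ``.year``/``.month``), ``red``, ``nir`` and ``qa`` attributes, e.g. the
    scenes of a generated landscape stack.
    """
    if season not in SEASON_WINDOWS:
        raise ValueError(f"unknown season {season!r}")
    lo, hi = SEASON_WINDOWS[season]
    selected = [
        s for s in scenes if s.date.year == year and lo <= s.date.month <= hi
    ]
    if not selected:
        raise ValueError(f"no scenes in the {season} {year} window")
    return max_composite(compute_ndvi(s.red, s.nir, s.qa) for s in selected)


def standardize_spei(series: pd.DataFrame, raw_col: str = "spei_raw") -> pd.DataFrame:
    """Z-score the raw anomaly within each season label (ddof=1).

    Returns a copy with a ``spei_z`` column.  Requires at least two distinct
    raw values per season; a constant series has no anomaly scale.
    """
    out = series.copy()
    zs = np.empty(len(out), dtype=float)
    for season, idx in out.groupby("season").groups.items():
        vals = out.loc[idx, raw_col].to_numpy(dtype=float)
        if len(vals) < 2 or np.ptp(vals) == 0:
            raise ValueError(
                f"season {season!r} needs >= 2 distinct raw values to standardize"
            )
        zs[out.index.get_indexer(idx)] = (vals - vals.mean()) / vals.std(ddof=1)
    out["spei_z"] = zs
    return out


def mean_raster_in_range(raster: Raster, geometry: "BaseGeometry") -> tuple[float, int]:
    """Mean over unmasked cells whose centres fall inside the polygon.

    Cell-centre-in-polygon rule, no partial-cell weighting.  Returns
    ``(mean, n_cells_used)``; raises if no unmasked cell centre is covered.
    """
    hr_geom = getattr(geometry, "geometry", geometry)
    X, Y = raster.grid.meshgrid()
    inside = shapely.contains_xy(hr_geom, X.ravel(), Y.ravel()).reshape(X.shape)
    usable = inside & ~raster.mask
    n = int(usable.sum())
    if n == 0:
        raise ValueError("no unmasked cell centres fall inside the polygon")
    return float(raster.values[usable].mean()), n
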