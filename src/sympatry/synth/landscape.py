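"""Synthetic landscape: riparian greenness gradient and seasonal scenes.

The landscape is a flat tropical dry forest crossed by a sinuous river.
Dry-season greenness (NDVI, computed downstream from RED/NIR) decays with
distance from the river, concentrating resources in riparian strips; the
wet season greens the whole scene and flattens the gradient.  Each seasonal
window contributes several noisy RED/NIR scenes with a QA contamination
mask, from which maximum composites are built downstream.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..grids import Grid, Raster
from ..rng import substream

__all__ = ["LandscapeConfig", "Scene", "LandscapeStack", "gen_landscape"]

_SCENE_MONTHS = {"dry": (2, 3, 4), "wet": (9, 10, 11)}


@dataclass
class LandscapeConfig:
    nx: int = 200
    ny: int = 200
    cell: float = 30.0                      # metres; Landsat-like resolution
    years: Sequence[int] = field(default_factory=lambda: (2018,))
    qa_fraction: float = 0.02               # fraction of cells flagged per scene
    river_amplitude: float = 600.0          # metres
    river_wavelength: float = 3500.0        # metres
    ndvi_dry_near: float = 0.65             # dry NDVI at the river
    ndvi_dry_far: float = 0.30              # dry NDVI far from the river
    ndvi_decay: float = 900.0               # metres, e-folding of the gradient
    ndvi_wet_mean: float = 0.68
    ndvi_wet_gradient: float = 0.03
    scene_noise_sd: float = 0.02            # per-scene NDVI-scale noise
    year_sd: float = 0.02                   # shared per-year greenness shift


@dataclass
class Scene:
    """One satellite overpass: RED/NIR reflectances plus a QA mask."""

    date: dt.date
    red: Raster
    nir: Raster
    qa: Raster  # 1.0 = contaminated


@dataclass
class LandscapeStack:
    grid: Grid
    scenes: list[Scene]
    riparian_distance: Raster
    config: "LandscapeConfig | None" = None

    def river_y(self, x: np.ndarray) -> np.ndarray:
        return self._river_mid + self._river_amp * np.sin(
            2 * np.pi * x / self._river_wavelength
        )

    _river_mid: float = 0.0
    _river_amp: float = 0.0
    _river_wavelength: float = 1.0


def _reflectances(grid: Grid, ndvi: np.ndarray, rng: np.random.Generator):
    ndvi = np.clip(ndvi, -0.9, 0.9)
    red = np.clip(0.10 + rng.normal(0.0, 0.01, size=grid.shape), 0.02, 0.5)
    nir = np.clip(red * (1.0 + ndvi) / (1.0 - ndvi), 0.0, 1.0)
    return Raster(grid, red), Raster(grid, nir)


def gen_landscape(config: LandscapeConfig | None = None, seed: int = 0) -> LandscapeStack:
    """Generate the raster stack for all configured years and both seasons."""
    config = config or LandscapeConfig()
    if config.cell <= 0:
        raise ValueError("cell size must be positive")
    if config.nx < 50 or config.ny < 50:
        raise ValueError("landscape grid must be at least 50x50 cells")
    rng = substream(seed, "landscape")
    grid = Grid(x0=0.0, y0=0.0, cell=config.cell, nx=config.nx, ny=config.ny)
    X, Y = grid.meshgrid()

    mid = 0.5 * config.ny * config.cell
    river = mid + config.river_amplitude * np.sin(2 * np.pi * X / config.river_wavelength)
    dist = np.abs(Y - river)
    riparian = Raster(grid, dist)

    gradient = np.exp(-dist / config.ndvi_decay)
    scenes: list[Scene] = []
    for year in config.years:
        year_shift = rng.normal(0.0, config.year_sd)
        for season, months in _SCENE_MONTHS.items():
            if season == "dry":
                base = (
                    config.ndvi_dry_far
                    + (config.ndvi_dry_near - config.ndvi_dry_far) * gradient
                )
            else:
                base = config.ndvi_wet_mean + config.ndvi_wet_gradient * gradient
            for month in months:
                ndvi = base + year_shift + rng.normal(
                    0.0, config.scene_noise_sd, size=grid.shape
                )
                red, nir = _reflectances(grid, ndvi, rng)
                qa = Raster(
                    grid,
                    (rng.random(grid.shape) < config.qa_fraction).astype(float),
                )
                scenes.append(Scene(dt.date(year, month, 15), red, nir, qa))

    stack = LandscapeStack(
        grid=grid, scenes=scenes, riparian_distance=riparian, config=config
    )
    stack._river_mid = mid
    stack._river_amp = config.river_amplitude
    stack._river_wavelength = config.river_wavelength
    return stack
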