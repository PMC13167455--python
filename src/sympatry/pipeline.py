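"""End-to-end orchestration: generate -> metrics -> models -> shifts -> report.

A run starts from a serialized configuration and one master seed, builds
the synthetic study system, computes every response and dyadic metric,
fits the full model suite, runs the range-shift driver analysis, and
writes tables plus a JSON summary into the output directory.  Identical
(config, seed) pairs reproduce every output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import environment as env
from .dyadic import (
    build_directed_records,
    classify_driver,
    delta_d,
    driver_proportion,
    overlap_zone,
    select_shift_events,
)
from .grids import Raster
from .rng import substream
from .spaceuse import UDGrid, daily_path_length, hr_contour
from .synth import (
    ForagingConfig,
    LandscapeConfig,
    SpaceUseConfig,
    gen_climate,
    gen_demography,
    gen_foraging,
    gen_landscape,
    gen_mm_data,
    gen_space_use,
    gen_srm_data,
)
from .synth.movement import UDSpec, mixture_product_integral
from .truth import GenerativeTruth
from .bayes import (
    GroupModelSpec,
    MMSpec,
    SRMSpec,
    fit_encounter_mm,
    fit_group_glmm,
    fit_srm,
    marginal_slope,
    seasonal_contrast,
    summarize,
)
from .bayes.glmm import coef_draws, size_slope_draws
from .bayes.mm import mm_coef_draws, season_slope_contrast
from .bayes.srm import conditional_neighbour_slope, neighbour_slope_draws, rho_draws

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Full scenario description; serialized into every run directory."""

    scenario: str = "default"
    n_groups: int = 12
    year_start: int = 2000
    year_stop: int = 2024            # exclusive
    seed: int = 0
    truth: GenerativeTruth = field(default_factory=GenerativeTruth)
    # spatial / metric settings
    grid_nx: int = 200
    grid_ny: int = 200
    grid_cell: float = 30.0
    contour_level: float = 0.95      # GPS-era ranges
    contour_level_sleep: float = 0.98
    revisit_radius: float = 30.0     # metres
    encounter_area_scale: float = 1.0
    # shift-analysis thresholds
    po_low: float = 0.25
    po_high: float = 0.45
    min_size_change: int = 5
    # representative evaluation points
    focal_sizes: tuple[float, ...] = (8, 21, 35)
    spei_values: tuple[float, ...] = (-1.5, 0.0, 1.5)
    # inference settings
    n_draws: int = 2000
    # stage switches
    fit_models: bool = True
    do_shifts: bool = True
    expansion_strength: float = 1.0  # scales the growth-coupled range sweep
    traj_days_per_season: int = 1
    individuals_per_group: int = 12
    follows_per_individual_season: int = 2

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_stop)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "truth" in data and isinstance(data["truth"], dict):
            data["truth"] = GenerativeTruth.from_dict(data["truth"])
        for key in ("focal_sizes", "spei_values"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class RunResult:
    config: RunConfig
    demography: pd.DataFrame
    climate: pd.DataFrame
    ud_table: pd.DataFrame
    responses: dict[str, pd.DataFrame]
    fits: dict
    summaries: dict
    shift_events: list
    outdir: Path | None


def _crop_raster(raster: Raster, bounds, pad_cells: int = 2) -> Raster:
    """Cut a raster to a bounding box (keeps zonal means fast)."""
    g = raster.grid
    x0, y0, x1, y1 = bounds
    i0 = max(0, int((y0 - g.y0) / g.cell) - pad_cells)
    i1 = min(g.ny, int(np.ceil((y1 - g.y0) / g.cell)) + pad_cells)
    j0 = max(0, int((x0 - g.x0) / g.cell) - pad_cells)
    j1 = min(g.nx, int(np.ceil((x1 - g.x0) / g.cell)) + pad_cells)
    from .grids import Grid

    sub = Grid(
        x0=g.x0 + j0 * g.cell,
        y0=g.y0 + i0 * g.cell,
        cell=g.cell,
        nx=max(1, j1 - j0),
        ny=max(1, i1 - i0),
    )
    return Raster(sub, raster.values[i0 : i0 + sub.ny, j0 : j0 + sub.nx])


def _zonal_mean(raster: Raster, geometry) -> float:
    try:
        cropped = _crop_raster(raster, geometry.bounds)
        val, _ = env.mean_raster_in_range(cropped, geometry)
        return val
    except ValueError:
        return float("nan")


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> RunResult:
    """Execute all stages; returns everything in memory, optionally on disk."""
    config.truth.validate()
    truth = config.truth
    seed = config.seed
    out = None
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")

    # ---- stage: generate -------------------------------------------------
    logger.info("stage generate (seed=%d)", seed)
    demography = gen_demography(config.n_groups, config.years, truth, seed)
    climate = gen_climate(config.years, truth, seed)
    lcfg = LandscapeConfig(
        nx=config.grid_nx,
        ny=config.grid_ny,
        cell=config.grid_cell,
        years=list(config.years),
    )
    landscape = gen_landscape(lcfg, seed)
    base_su = SpaceUseConfig()
    sucfg = SpaceUseConfig(
        traj_days_per_season=config.traj_days_per_season,
        expansion_sweep=base_su.expansion_sweep * config.expansion_strength,
        expansion_close=base_su.expansion_close * config.expansion_strength,
    )
    space = gen_space_use(demography, landscape, climate, truth, seed, sucfg)
    foraging = gen_foraging(
        demography,
        climate,
        truth,
        seed,
        ForagingConfig(
            individuals_per_group=config.individuals_per_group,
            follows_per_individual_season=config.follows_per_individual_season,
        ),
    )
    srm_records = gen_srm_data(truth, demography, seed, seasonal=True)

    ud_table = space.ud_table()
    rng_obs = substream(seed, "observation")

    # ---- stage: metrics --------------------------------------------------
    logger.info("stage metrics")
    grid = landscape.grid
    by_gs = {(u.group_id, u.year, u.season): u for u in space.ud_specs}

    # seasonal NDVI composites per year
    composites: dict[tuple[int, str], Raster] = {}
    for year in config.years:
        for season in ("dry", "wet"):
            composites[(year, season)] = env.seasonal_composite(
                landscape.scenes, year, season
            )

    # seasonal contours (sleep-range level); the wet-season range — the
    # largest, resource-rich range of the year — stands in as the yearly
    # range for the shift analysis
    seasonal_hr = {}
    for (gid, year, season), spec in by_gs.items():
        ud = UDGrid(grid, spec.density_on(grid))
        seasonal_hr[(gid, f"{year}-{season}")] = hr_contour(
            ud, config.contour_level, group_id=gid, period=f"{year}-{season}"
        )
    yearly_hr = {
        (gid, str(year)): hr
        for (gid, period), hr in seasonal_hr.items()
        for year in [int(period.split("-")[0])]
        if period.endswith("wet")
    }

    # group-level response tables
    hra_rows, rev_rows, ndvi_rows = [], [], []
    for u in space.ud_specs:
        log_area_obs = np.log(u.area95_true) + rng_obs.normal(0, truth.noise.hra_obs_se)
        hra_rows.append(
            {
                "group_id": u.group_id,
                "year": u.year,
                "season": u.season,
                "size_z": u.size_z,
                "spei_z": u.spei_z,
                "hra": float(np.exp(log_area_obs)),
                "hra_log_se": truth.noise.hra_obs_se,
            }
        )
        rev_rows.append(
            {
                "group_id": u.group_id,
                "year": u.year,
                "season": u.season,
                "size_z": u.size_z,
                "spei_z": u.spei_z,
                "revisit": config.revisit_radius * u.speed * mixture_product_integral(u, u),
            }
        )
        hr = seasonal_hr[(u.group_id, f"{u.year}-{u.season}")]
        mean_ndvi = _zonal_mean(composites[(u.year, u.season)], hr.geometry)
        if np.isfinite(mean_ndvi):
            # beta-distributed observation noise around the zonal mean
            phi = truth.noise.ndvi_phi
            m = float(np.clip(mean_ndvi, 0.02, 0.98))
            obs = float(rng_obs.beta(m * phi, (1 - m) * phi))
            ndvi_rows.append(
                {
                    "group_id": u.group_id,
                    "year": u.year,
                    "season": u.season,
                    "size_z": u.size_z,
                    "spei_z": u.spei_z,
                    "hr_ndvi": obs,
                }
            )
    hra_df = pd.DataFrame(hra_rows)
    rev_df = pd.DataFrame(rev_rows)
    ndvi_df = pd.DataFrame(ndvi_rows)

    # daily path lengths from trajectories
    dpl_rows = []
    if len(space.trajectories):
        for (gid, date), day in space.trajectories.groupby(["group_id", "date"]):
            pl = daily_path_length(
                day["t"].to_numpy(), day[["x", "y"]].to_numpy(),
                group_id=gid, date=str(date), n_boot=30, seed=seed,
            )
            if not pl.qc_pass:
                continue
            meta = day.iloc[0]
            dem_row = demography[
                (demography["group_id"] == gid)
                & (demography["year"] == meta["year"])
                & (demography["season"] == meta["season"])
            ].iloc[0]
            dpl_rows.append(
                {
                    "group_id": gid,
                    "year": int(meta["year"]),
                    "season": meta["season"],
                    "size_z": float(dem_row["size_z"]),
                    "spei_z": float(
                        climate.set_index(["year", "season"]).loc[
                            (meta["year"], meta["season"]), "spei_z"
                        ]
                    ),
                    "dpl": pl.length,
                    "dpl_log_se": max(pl.length_se / pl.length, 1e-3)
                    if np.isfinite(pl.length_se)
                    else 0.05,
                }
            )
    dpl_df = pd.DataFrame(dpl_rows)

    # seasonal dyadic geometry: overlap zones for MM covariates
    season_sizes = demography.copy()
    season_sizes["period"] = (
        season_sizes["year"].astype(str) + "-" + season_sizes["season"]
    )
    mm_cov_rows = []
    seasonal_groups: dict[str, list[str]] = {}
    for gid, period in seasonal_hr:
        seasonal_groups.setdefault(period, []).append(gid)
    for period, gids in sorted(seasonal_groups.items()):
        year, season = int(period.split("-")[0]), period.split("-")[1]
        comp = composites[(year, season)]
        gids = sorted(gids)
        for i, a in enumerate(gids):
            for b in gids[i + 1 :]:
                zone = overlap_zone(
                    seasonal_hr[(a, period)], seasonal_hr[(b, period)], comp
                )
                if zone.area <= 0:
                    continue
                mm_cov_rows.append(
                    {
                        "dyad_id": f"{a}~{b}",
                        "period": period,
                        "overlap_area": zone.area,
                        "overlap_ndvi": zone.mean_ndvi,
                    }
                )
    mm_cov = pd.DataFrame(mm_cov_rows)
    if len(mm_cov):
        la = np.log(mm_cov["overlap_area"])
        mm_cov["overlap_area_z"] = (la - la.mean()) / la.std(ddof=1)
        nd = mm_cov["overlap_ndvi"].fillna(mm_cov["overlap_ndvi"].mean())
        sd = nd.std(ddof=1)
        mm_cov["overlap_ndvi_z"] = 0.0 if not sd > 0 else (nd - nd.mean()) / sd
    mm_records = gen_mm_data(
        truth, demography, seed, seasonal=True,
        covariates=mm_cov if len(mm_cov) else None,
    )

    # annual geometric PO panel for the shift analysis
    annual_sizes = demography[demography["season"] == "dry"][
        ["group_id", "year", "size", "size_z"]
    ].copy()
    annual_sizes["period"] = annual_sizes["year"].astype(str)
    po_panel = build_directed_records(yearly_hr, annual_sizes)

    responses = {
        "foraging": foraging,
        "hra": hra_df,
        "revisit": rev_df,
        "hr_ndvi": ndvi_df,
        "dpl": dpl_df,
        "srm": srm_records,
        "mm": mm_records,
        "po_panel": po_panel,
        "mm_covariates": mm_cov,
    }

    # ---- stage: models ---------------------------------------------------
    fits: dict = {}
    summaries: dict = {}
    if config.fit_models:
        logger.info("stage models")
        fits["intake"] = fit_group_glmm(
            GroupModelSpec(
                response="bites",
                family="negative_binomial",
                offset="seconds_in_view",
                seasonal=True,
                spei=True,
                extra_varying="individual_id",
            ),
            foraging,
            seed=seed,
            n_draws=config.n_draws,
        )
        fits["hra"] = fit_group_glmm(
            GroupModelSpec(
                response="hra", family="gamma", me_se="hra_log_se", seasonal=True
            ),
            hra_df,
            seed=seed,
            n_draws=config.n_draws,
        )
        fits["revisit"] = fit_group_glmm(
            GroupModelSpec(response="revisit", family="gamma", seasonal=True),
            rev_df,
            seed=seed,
            n_draws=config.n_draws,
        )
        fits["hr_ndvi"] = fit_group_glmm(
            GroupModelSpec(
                response="hr_ndvi",
                family="beta",
                seasonal=True,
                spei=True,
                extra_varying="year",
            ),
            ndvi_df,
            seed=seed,
            n_draws=config.n_draws,
        )
        if len(dpl_df) >= 20:
            fits["dpl"] = fit_group_glmm(
                GroupModelSpec(
                    response="dpl", family="gamma", me_se="dpl_log_se", seasonal=True
                ),
                dpl_df,
                seed=seed,
                n_draws=config.n_draws,
            )
        size_stats = (
            float(demography["size"].mean()),
            float(demography["size"].std(ddof=1)),
        )
        fits["srm"] = fit_srm(
            SRMSpec(seasonal=True),
            srm_records,
            seed=seed,
            n_draws=config.n_draws,
            size_mean=size_stats[0],
            size_sd=size_stats[1],
        )
        fits["mm"] = fit_encounter_mm(
            MMSpec(seasonal=True), mm_records, seed=seed, n_draws=config.n_draws
        )

        summaries["marginal_slopes"] = {
            resp: {
                f"{season},spei={spei:g}": marginal_slope(fits[resp], season, spei).as_dict()
                for season in ("dry", "wet")
                for spei in (config.spei_values if resp in ("intake", "hr_ndvi") else (0.0,))
            }
            for resp in ("intake", "hra", "revisit", "hr_ndvi")
        }
        summaries["seasonal_contrasts"] = {
            resp: seasonal_contrast(fits[resp]).as_dict()
            for resp in ("intake", "hra", "revisit", "hr_ndvi")
        }
        summaries["neighbour_slopes"] = [
            s.as_dict()
            for s in conditional_neighbour_slope(fits["srm"], config.focal_sizes)
        ]
        summaries["srm_rho"] = {
            "rho_dd": summarize(rho_draws(fits["srm"], "dd"), "rho_dd").as_dict(),
            "rho_gr": summarize(rho_draws(fits["srm"], "gr"), "rho_gr").as_dict(),
        }
        summaries["mm_effects"] = {
            nm: summarize(mm_coef_draws(fits["mm"], nm), nm).as_dict()
            for nm in fits["mm"].meta["coef_names"]
        }
        summaries["mm_season_contrasts"] = {
            term: season_slope_contrast(fits["mm"], term).as_dict()
            for term in ("size_diff", "area", "ndvi")
        }

        # sign agreement with the generative truth
        checks = {
            "size_intake": (
                float(np.median(size_slope_draws(fits["intake"], "dry", 0.0))),
                np.sign(truth.beta_size_intake),
            ),
            "size_hra": (
                float(np.median(coef_draws(fits["hra"], "b_size"))),
                np.sign(truth.beta_size_hra),
            ),
            "size_revisit": (
                float(np.median(coef_draws(fits["revisit"], "b_size"))),
                np.sign(truth.beta_size_revisit),
            ),
            "neighbour_po_small_focal": (
                float(np.median(neighbour_slope_draws(fits["srm"], config.focal_sizes[0]))),
                1.0,
            ),
            "er_area_dry_contrast": (
                float(season_slope_contrast(fits["mm"], "area").median),
                -np.sign(truth.mm.b_area_dry),
            ),
            "size_ndvi_dry_wet_spei": (
                float(np.median(size_slope_draws(fits["hr_ndvi"], "dry", 1.5))),
                np.sign(
                    truth.beta_size_ndvi_dry + 1.5 * truth.spei_interactions.ndvi_dry
                ),
            ),
        }
        summaries["sign_checks"] = {
            name: {
                "median": med,
                "truth_sign": int(sign),
                "agree": bool(np.sign(med) == sign),
            }
            for name, (med, sign) in checks.items()
        }

    # ---- stage: shifts ---------------------------------------------------
    shift_events = []
    if config.do_shifts:
        logger.info("stage shifts")
        shift_events = select_shift_events(
            po_panel, config.po_low, config.po_high, config.min_size_change
        )
        for ev in shift_events:
            try:
                hr_f = yearly_hr[(ev.focal_id, ev.period_t)]
                hr_n = yearly_hr[(ev.neighbour_id, ev.period_t)]
                zone_t = overlap_zone(hr_f, hr_n).geometry
                zone_u = overlap_zone(
                    yearly_hr[(ev.focal_id, ev.period_ti)],
                    yearly_hr[(ev.neighbour_id, ev.period_ti)],
                ).geometry
                bigger = ev.larger_becoming
                smaller = ev.neighbour_id if bigger == ev.focal_id else ev.focal_id
                ev.delta_d_bigger = delta_d(
                    yearly_hr[(bigger, ev.period_t)], zone_t, zone_u
                )
                ev.delta_d_smaller = delta_d(
                    yearly_hr[(smaller, ev.period_t)], zone_t, zone_u
                )
                classify_driver(ev)
            except (KeyError, ValueError):
                continue
        classified = [e for e in shift_events if e.driver]
        if classified:
            prop, ci, n_used = driver_proportion(classified)
            summaries["driver_proportion"] = {
                "proportion": prop,
                "ci95": list(ci),
                "n_events": n_used,
            }

    # ---- stage: report ---------------------------------------------------
    if out is not None:
        logger.info("stage report -> %s", out)
        demography.to_csv(out / "demography.csv", index=False)
        climate.to_csv(out / "climate.csv", index=False)
        ud_table.to_csv(out / "ud_table.csv", index=False)
        for name, df in responses.items():
            if isinstance(df, pd.DataFrame) and len(df):
                df.to_csv(out / f"{name}.csv", index=False)
        if shift_events:
            pd.DataFrame([asdict(e) for e in shift_events]).to_csv(
                out / "shift_events.csv", index=False
            )
        with open(out / "summary.json", "w") as fh:
            json.dump(summaries, fh, indent=2, default=float)
        if config.fit_models:
            _effect_figure(summaries, out / "effects.png")

    return RunResult(
        config=config,
        demography=demography,
        climate=climate,
        ud_table=ud_table,
        responses=responses,
        fits=fits,
        summaries=summaries,
        shift_events=shift_events,
        outdir=out,
    )


def _effect_figure(summaries: dict, path: Path) -> None:
    """Posterior-interval dot plot of the headline effects."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = []
    for resp, c in summaries.get("seasonal_contrasts", {}).items():
        rows.append((f"{resp}: wet-dry size slope", c["median"], c["hpdi89_lo"], c["hpdi89_hi"]))
    for s in summaries.get("neighbour_slopes", []):
        rows.append((s["label"], s["median"], s["hpdi89_lo"], s["hpdi89_hi"]))
    for term, c in summaries.get("mm_season_contrasts", {}).items():
        rows.append((f"ER {term}: wet-dry", c["median"], c["hpdi89_lo"], c["hpdi89_hi"]))
    if not rows:
        return
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(rows) + 1.2))
    ys = np.arange(len(rows))[::-1]
    for y, (label, med, lo, hi) in zip(ys, rows):
        ax.plot([lo, hi], [y, y], color="steelblue", lw=2)
        ax.plot(med, y, "o", color="black", ms=4)
    ax.axvline(0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(ys)
    ax.set_yticklabels([r[0] for r in rows], fontsize=8)
    ax.set_xlabel("posterior median and 89% HPDI")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
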