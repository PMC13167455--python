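"""Group space use: utilization distributions, trajectories, sleep sites.

Each group-season receives an isotropic bivariate-Gaussian(-mixture)
utilization distribution (UD).  The log of the true 95% area follows a
linear model in z-scored group size plus a season shift, so the
size -> home-range-area effect is known exactly.  Dry-season UD centres are
pulled toward the river, with larger groups placed on greener cells at a
strength modulated by the seasonal climate anomaly; this encodes the
size -> range-greenness effect spatially.  Movement within a season is a
stationary Ornstein-Uhlenbeck (OU) process around the UD centre whose
stationary spread equals the UD spread, and sleep sites are drawn from the
UD core.

Group centres also drift toward their nearest neighbour in proportion to
their census growth (``expansion_pull``), so growing groups encroach on
neighbours — the substrate of the range-shift driver analysis.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..rng import substream
from ..truth import GenerativeTruth
from .landscape import LandscapeStack

__all__ = [
    "UDSpec",
    "SpaceUse",
    "SpaceUseConfig",
    "gen_space_use",
    "simulate_ou",
    "mixture_product_integral",
]

logger = logging.getLogger(__name__)

#: chi-square(2 df) quantile at 0.95: area of the 95% ellipse is pi*sigma^2*this
CHI2_95 = 5.991464547107979


@dataclass
class UDSpec:
    """Parameters of one group-season UD (isotropic Gaussian mixture)."""

    group_id: str
    year: int
    season: str
    weights: np.ndarray          # (k,)
    means: np.ndarray            # (k, 2) metres
    sds: np.ndarray              # (k,) isotropic component sd, metres
    area95_true: float           # m^2, the generative 95% home-range area
    speed: float                 # mean travel speed, m/s
    size: int
    size_z: float
    spei_z: float

    def density_at(self, xy: np.ndarray) -> np.ndarray:
        """Mixture density at (n, 2) points."""
        xy = np.atleast_2d(xy)
        out = np.zeros(len(xy))
        for w, mu, sd in zip(self.weights, self.means, self.sds):
            d2 = ((xy - mu) ** 2).sum(axis=1)
            out += w * np.exp(-0.5 * d2 / sd**2) / (2 * np.pi * sd**2)
        return out

    def density_on(self, grid) -> np.ndarray:
        """Density on a grid's cell centres, renormalized to unit mass."""
        X, Y = grid.meshgrid()
        dens = self.density_at(np.column_stack([X.ravel(), Y.ravel()]))
        dens = dens.reshape(grid.shape)
        total = dens.sum() * grid.cell_area
        if total <= 0:
            raise ValueError("UD has no mass on the grid")
        return dens / total

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=n, p=self.weights)
        pts = self.means[comp] + rng.normal(size=(n, 2)) * self.sds[comp, None]
        return pts

    def self_overlap(self) -> float:
        """Closed-form integral of the squared density."""
        return mixture_product_integral(self, self)


def mixture_product_integral(a: UDSpec, b: UDSpec) -> float:
    """Closed form for the UD-product integral of two Gaussian mixtures.

    For Gaussian components the product integral is the Gaussian density of
    the mean difference under the summed covariance, summed bilinearly over
    component pairs.
    """
    total = 0.0
    for wa, mua, sda in zip(a.weights, a.means, a.sds):
        for wb, mub, sdb in zip(b.weights, b.means, b.sds):
            s2 = sda**2 + sdb**2
            d2 = float(((mua - mub) ** 2).sum())
            total += wa * wb * math.exp(-0.5 * d2 / s2) / (2 * math.pi * s2)
    return total


def simulate_ou(
    center: np.ndarray,
    sd: float,
    tau: float,
    dt_s: float,
    n_steps: int,
    rng: np.random.Generator,
    start: np.ndarray | None = None,
) -> np.ndarray:
    """Exact discrete-time sample of a stationary 2-D OU process.

    ``sd`` is the stationary standard deviation per axis; ``tau`` the
    relaxation time scale (s); ``dt_s`` the sampling interval (s).
    """
    if sd <= 0 or tau <= 0 or dt_s <= 0 or n_steps < 1:
        raise ValueError("sd, tau, dt_s must be positive and n_steps >= 1")
    a = math.exp(-dt_s / tau)
    innov_sd = sd * math.sqrt(1.0 - a * a)
    center = np.asarray(center, dtype=float)
    out = np.empty((n_steps, 2))
    out[0] = center + rng.normal(0.0, sd, 2) if start is None else start
    noise = rng.normal(0.0, innov_sd, size=(n_steps - 1, 2))
    for t in range(1, n_steps):
        out[t] = center + a * (out[t - 1] - center) + noise[t - 1]
    return out


@dataclass
class SpaceUseConfig:
    n_components: int = 1          # UD mixture components per group-season
    component_spread: float = 1.2  # inter-component offset in units of sd
    expansion_sweep: float = 0.04  # radians of perimeter sweep per individual
    expansion_close: float = 0.012  # fractional radial closure per individual
    ou_tau: float = 3600.0         # OU relaxation time, s
    traj_days_per_season: int = 2
    traj_dt: float = 300.0         # sampling interval, s (5 min)
    traj_hours: float = 12.0       # tracked hours per day
    wet_offset_sd: float = 1200.0  # between-group wet-season offset from river, m
    wet_jitter_sd: float = 150.0   # year-to-year wobble of the wet centre, m
    dry_jitter_sd: float = 120.0   # placement noise on the dry target distance
    margin_sds: float = 2.0        # keep centres this many sds inside the grid


@dataclass
class SpaceUse:
    ud_specs: list[UDSpec]
    trajectories: pd.DataFrame
    sleep_sites: pd.DataFrame

    def ud_table(self) -> pd.DataFrame:
        rows = [
            {
                "group_id": u.group_id,
                "year": u.year,
                "season": u.season,
                "size": u.size,
                "size_z": u.size_z,
                "spei_z": u.spei_z,
                "area95_true": u.area95_true,
                "speed": u.speed,
                "cx": float(np.average(u.means[:, 0], weights=u.weights)),
                "cy": float(np.average(u.means[:, 1], weights=u.weights)),
            }
            for u in self.ud_specs
        ]
        return pd.DataFrame(rows)


def _disc_mean(field: np.ndarray, grid, cx: float, cy: float, radius: float) -> float:
    """Mean of a raster field over a disc (cells whose centres fall inside)."""
    j0 = max(0, int((cx - radius - grid.x0) / grid.cell))
    j1 = min(grid.nx, int((cx + radius - grid.x0) / grid.cell) + 2)
    i0 = max(0, int((cy - radius - grid.y0) / grid.cell))
    i1 = min(grid.ny, int((cy + radius - grid.y0) / grid.cell) + 2)
    if i1 <= i0 or j1 <= j0:
        return float("nan")
    xs = grid.x0 + (np.arange(j0, j1) + 0.5) * grid.cell
    ys = grid.y0 + (np.arange(i0, i1) + 0.5) * grid.cell
    Xs, Ys = np.meshgrid(xs, ys)
    mask = (Xs - cx) ** 2 + (Ys - cy) ** 2 <= radius * radius
    if not mask.any():
        return float("nan")
    return float(field[i0:i1, j0:j1][mask].mean())


def _dry_target_distance(
    landscape: LandscapeStack,
    base_field: np.ndarray,
    x: float,
    side: float,
    target_ndvi: float,
    sigma: float,
) -> float:
    """Distance from the river whose range-mean dry greenness hits the target.

    The downstream response is the zonal mean of the dry composite over the
    95% contour — a disc of radius ~2.45 sigma — so the inversion bisects
    on the disc mean of the noiseless dry greenness field itself, which
    keeps the mapping unbiased in range size (hence group size) and honest
    about the river's meander within a range.
    """
    grid = landscape.grid
    radius = np.sqrt(CHI2_95) * sigma
    y_river = float(landscape.river_y(np.array([x]))[0])

    def disc(d: float) -> float:
        return _disc_mean(base_field, grid, x, y_river + side * d, radius)

    lo, hi = 0.0, 2500.0
    f_lo, f_hi = disc(lo), disc(hi)
    if not np.isfinite(f_lo) or target_ndvi >= f_lo:
        return lo
    if not np.isfinite(f_hi) or target_ndvi <= f_hi:
        return hi
    for _ in range(18):  # field is decreasing in distance
        mid = 0.5 * (lo + hi)
        if disc(mid) > target_ndvi:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gen_space_use(
    demography: pd.DataFrame,
    landscape: LandscapeStack,
    climate: pd.DataFrame,
    truth: GenerativeTruth | None = None,
    seed: int = 0,
    config: SpaceUseConfig | None = None,
) -> SpaceUse:
    """Generate UD parameters, trajectories and sleep sites for all records."""
    truth = truth or GenerativeTruth()
    truth.validate()
    config = config or SpaceUseConfig()
    rng = substream(seed, "space_use")

    dem_years = set(demography["year"])
    clim = climate.set_index(["year", "season"])
    if not dem_years <= set(climate["year"]):
        raise ValueError("climate series must cover all demography years")

    grid = landscape.grid
    lx = grid.nx * grid.cell
    ly = grid.ny * grid.cell
    groups = sorted(demography["group_id"].unique())
    # home anchors spread along the river
    anchor_x = {g: (i + 0.5) / len(groups) * lx for i, g in enumerate(groups)}
    river_side = {g: rng.choice([-1.0, 1.0]) for g in groups}
    # each group's wet range sits at a persistent offset from the river;
    # only a modest wobble is redrawn per year (ranges are stable in life)
    wet_offset = {g: rng.normal(0.0, config.wet_offset_sd) for g in groups}
    # expansion dynamics: a growing group sweeps around its nearest
    # neighbour's range perimeter (tangential orbit with a slow radial
    # closure); this flanking encroachment is what moves the overlap zone
    # along the expander's sight-line but only laterally for the neighbour
    partner = {
        g: min((h for h in groups if h != g), key=lambda h: abs(anchor_x[h] - anchor_x[g]))
        for g in groups
    }
    sweep_sign = {g: rng.choice([-1.0, 1.0]) for g in groups}
    theta = {g: 0.0 for g in groups}
    closure = {g: 0.0 for g in groups}
    last_size: dict[str, int] = {}

    def wet_base(g: str) -> np.ndarray:
        ax = anchor_x[g]
        return np.array(
            [ax, float(landscape.river_y(np.array([ax]))[0]) + wet_offset[g]]
        )

    from .landscape import LandscapeConfig

    lc = landscape.config or LandscapeConfig()
    curve = (lc.ndvi_dry_far, lc.ndvi_dry_near, lc.ndvi_decay)
    base_dry = curve[0] + (curve[1] - curve[0]) * np.exp(
        -landscape.riparian_distance.values / curve[2]
    )

    speed_slope = truth.beta_size_revisit + truth.beta_size_hra
    ud_specs: list[UDSpec] = []
    traj_rows: list[pd.DataFrame] = []
    sleep_rows: list[dict] = []

    annual = demography[demography["season"] == "dry"][
        ["group_id", "year", "size"]
    ].set_index(["group_id", "year"])["size"]

    for year in sorted(dem_years):
        # accumulate each group's sweep around its neighbour with growth
        for g in groups:
            if (g, year) not in annual.index:
                continue
            size_now = int(annual.loc[(g, year)])
            growth = size_now - last_size.get(g, size_now)
            last_size[g] = size_now
            if growth != 0 and len(groups) > 1:
                theta[g] += sweep_sign[g] * config.expansion_sweep * growth
                closure[g] += config.expansion_close * growth

        for season in ("dry", "wet"):
            spei_z = float(clim.loc[(year, season), "spei_z"])
            season_df = demography[
                (demography["year"] == year) & (demography["season"] == season)
            ]
            for rec in season_df.itertuples():
                if pd.isna(rec.size):
                    logger.warning(
                        "skipping %s %s %s: size missing", rec.group_id, year, season
                    )
                    continue
                size_z = float(rec.size_z)
                log_area = (
                    truth.hra_log_area
                    + (truth.hra_wet if season == "wet" else 0.0)
                    + truth.beta_size_hra * size_z
                    + rng.normal(0.0, truth.noise.hra_log_sd)
                )
                area = math.exp(log_area)
                sd_total = math.sqrt(area / (math.pi * CHI2_95))

                x = anchor_x[rec.group_id]
                if season == "dry":
                    ndvi_slope = truth.beta_size_ndvi_dry + (
                        truth.spei_interactions.ndvi_dry * spei_z
                    )
                    # target zonal-mean NDVI on the logit scale, so the
                    # observed logit greenness carries the stated slope
                    logit_target = truth.ndvi_logit_dry + ndvi_slope * size_z
                    target_ndvi = 1.0 / (1.0 + math.exp(-logit_target))
                    side = river_side[rec.group_id]
                    d_star = _dry_target_distance(
                        landscape, base_dry, x, side, target_ndvi, sd_total
                    )
                    d_star = max(0.0, d_star + rng.normal(0.0, config.dry_jitter_sd))
                    y = float(landscape.river_y(np.array([x]))[0]) + side * d_star
                else:
                    g = rec.group_id
                    base = wet_base(g)
                    rel = base - wet_base(partner[g])
                    th = theta[g]
                    rot = np.array(
                        [[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]
                    )
                    shrink = float(np.clip(1.0 - closure[g], 0.55, 1.2))
                    pos = (
                        wet_base(partner[g])
                        + shrink * (rot @ rel)
                        + rng.normal(0.0, config.wet_jitter_sd, 2)
                    )
                    x, y = float(pos[0]), float(pos[1])

                margin = config.margin_sds * sd_total
                x = float(np.clip(x, margin, lx - margin))
                y = float(np.clip(y, margin, ly - margin))

                k = config.n_components
                if k == 1:
                    weights = np.array([1.0])
                    means = np.array([[x, y]])
                    sds = np.array([sd_total])
                else:
                    weights = np.full(k, 1.0 / k)
                    angles = rng.uniform(0, 2 * np.pi)
                    offs = config.component_spread * sd_total * np.column_stack(
                        [
                            np.cos(angles + 2 * np.pi * np.arange(k) / k),
                            np.sin(angles + 2 * np.pi * np.arange(k) / k),
                        ]
                    )
                    means = np.array([x, y]) + offs
                    # shrink component sds so the overall spread stays ~sd_total
                    sds = np.full(k, sd_total / math.sqrt(1 + config.component_spread**2))

                speed = math.exp(
                    truth.speed_log
                    + speed_slope * size_z
                    + rng.normal(0.0, truth.noise.revisit_log_sd)
                )
                spec = UDSpec(
                    group_id=rec.group_id,
                    year=int(year),
                    season=season,
                    weights=weights,
                    means=means,
                    sds=sds,
                    area95_true=(
                        area if k == 1 else _numeric_area95(weights, means, sds)
                    ),
                    speed=speed,
                    size=int(rec.size),
                    size_z=size_z,
                    spei_z=spei_z,
                )
                ud_specs.append(spec)

                # trajectories + sleep sites
                month = 3 if season == "dry" else 10
                steps = int(config.traj_hours * 3600 / config.traj_dt) + 1
                for day in range(config.traj_days_per_season):
                    date = dt.date(int(year), month, 1 + day)
                    comp = rng.choice(k, p=weights)
                    pts = simulate_ou(
                        means[comp], float(sds[comp]), config.ou_tau,
                        config.traj_dt, steps, rng,
                    )
                    traj_rows.append(
                        pd.DataFrame(
                            {
                                "group_id": rec.group_id,
                                "year": int(year),
                                "season": season,
                                "date": date.isoformat(),
                                "t": np.arange(steps) * config.traj_dt,
                                "x": pts[:, 0],
                                "y": pts[:, 1],
                            }
                        )
                    )
                    core = means[comp] + rng.normal(0.0, 0.5 * sds[comp], 2)
                    sleep_rows.append(
                        {
                            "group_id": rec.group_id,
                            "year": int(year),
                            "season": season,
                            "date": date.isoformat(),
                            "x": core[0],
                            "y": core[1],
                        }
                    )

    trajectories = (
        pd.concat(traj_rows, ignore_index=True) if traj_rows else pd.DataFrame()
    )
    return SpaceUse(ud_specs, trajectories, pd.DataFrame(sleep_rows))


def _numeric_area95(weights, means, sds) -> float:
    """95% highest-density area of a mixture, by dense local quadrature."""
    span = float(np.max(sds)) * 5 + float(np.ptp(means, axis=0).max())
    cx, cy = means.mean(axis=0)
    n = 400
    xs = np.linspace(cx - span, cx + span, n)
    ys = np.linspace(cy - span, cy + span, n)
    X, Y = np.meshgrid(xs, ys)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    dens = np.zeros(len(pts))
    for w, mu, sd in zip(weights, means, sds):
        d2 = ((pts - mu) ** 2).sum(axis=1)
        dens += w * np.exp(-0.5 * d2 / sd**2) / (2 * np.pi * sd**2)
    cell = (xs[1] - xs[0]) * (ys[1] - ys[0])
    order = np.argsort(dens)[::-1]
    cum = np.cumsum(dens[order]) * cell
    k = int(np.searchsorted(cum, 0.95)) + 1
    return k * cell
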