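"""Pairwise spatial metrics between group home ranges.

Directed proportional overlap PO_fn = IA_fn / HRA_f is computed on contour
polygons (intersection area over the focal polygon's area), so IA is
symmetric while PO is not.  The encounter rate is the UD-product integral
scaled to a reference area — the relative probability that both groups
occupy the same unit area at the same moment — computed on full UD
surfaces and exactly symmetric.  Range-shift events are dyad-period pairs
where overlap jumps from under 25% to over 45% while relative group size
changes by at least 5 individuals; the group whose distance to the overlap
centroid changed more (larger |dD|) is classified as the driver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import MultiPolygon, Polygon
from shapely.geometry.base import BaseGeometry

from .environment import mean_raster_in_range
from .grids import Raster
from .spaceuse import HomeRange, UDGrid, fit_ud

__all__ = [
    "POResult",
    "OverlapZone",
    "EncounterRate",
    "ShiftEvent",
    "proportional_overlap",
    "overlap_zone",
    "encounter_rate",
    "delta_d",
    "select_shift_events",
    "classify_driver",
    "driver_proportion",
    "build_directed_records",
]


@dataclass
class POResult:
    po: float
    ia: float          # intersection area, m^2
    hra_focal: float   # focal polygon area, m^2


@dataclass
class OverlapZone:
    geometry: BaseGeometry
    area: float
    mean_ndvi: float   # NaN when the zone is empty or fully masked
    n_cells: int


@dataclass
class EncounterRate:
    er: float
    se: float
    area_scale: float


@dataclass
class ShiftEvent:
    pair_id: str
    focal_id: str                 # reporting direction of the PO jump
    neighbour_id: str
    period_t: str
    period_ti: str
    po_before: float
    po_after: float
    size_change_net: int          # change in (focal - neighbour) size
    larger_becoming: str          # group that became relatively larger
    delta_d_bigger: float = float("nan")
    delta_d_smaller: float = float("nan")
    driver: str | None = None


def _geom(hr) -> BaseGeometry:
    return hr.geometry if isinstance(hr, HomeRange) else hr


def proportional_overlap(hr_f, hr_n) -> POResult:
    """PO_fn = intersection area over focal range area (asymmetric)."""
    gf, gn = _geom(hr_f), _geom(hr_n)
    hra = gf.area
    if hra <= 0:
        raise ValueError("focal range polygon has zero area")
    ia = gf.intersection(gn).area
    po = ia / hra
    if po > 1.0:
        if po > 1.0 + 1e-9:
            raise ValueError(f"PO={po} exceeds 1 beyond rounding noise")
        po = 1.0
    return POResult(po=float(po), ia=float(ia), hra_focal=float(hra))


def overlap_zone(hr_f, hr_n, ndvi: Raster | None = None) -> OverlapZone:
    """Intersection polygon with its area and zonal mean greenness."""
    zone = _geom(hr_f).intersection(_geom(hr_n))
    if zone.is_empty or zone.area == 0:
        return OverlapZone(Polygon(), 0.0, float("nan"), 0)
    mean_val, n = float("nan"), 0
    if ndvi is not None:
        try:
            mean_val, n = mean_raster_in_range(ndvi, zone)
        except ValueError:
            pass  # zone smaller than a cell or fully masked
    return OverlapZone(zone, float(zone.area), mean_val, n)


def encounter_rate(
    ud_i: UDGrid,
    ud_j: UDGrid,
    area_scale: float = 1.0,
    points_i: np.ndarray | None = None,
    points_j: np.ndarray | None = None,
    n_boot: int = 0,
    seed: int = 0,
) -> EncounterRate:
    """area_scale x integral of p_i p_j over the shared grid (symmetric).

    With both point sets given, the SE comes from jointly bootstrapping the
    points and recomputing the product integral.
    """
    if ud_i.grid != ud_j.grid:
        raise ValueError("UDs must share an identical grid")
    cell_area = ud_i.grid.cell_area
    er = float(area_scale * (ud_i.density * ud_j.density).sum() * cell_area)
    se = float("nan")
    if points_i is not None and points_j is not None and n_boot > 0:
        rng = np.random.default_rng(seed)
        vals = []
        for _ in range(n_boot):
            pi = points_i[rng.integers(0, len(points_i), len(points_i))]
            pj = points_j[rng.integers(0, len(points_j), len(points_j))]
            di = fit_ud(pi, ud_i.grid, bandwidth=ud_i.bandwidth)
            dj = fit_ud(pj, ud_j.grid, bandwidth=ud_j.bandwidth)
            vals.append(area_scale * (di.density * dj.density).sum() * cell_area)
        se = float(np.std(vals, ddof=1))
    return EncounterRate(er=er, se=se, area_scale=area_scale)


def delta_d(hr_g_t, overlap_t, overlap_ti) -> float:
    """Change in distance from the group's centroid to the overlap centroid.

    dD = D_{t+i} - D_t where D is the distance from the group's range
    centroid at time t to the overlap-zone centroid at the stated time.
    Positive values mean the overlap centroid ended up farther from this
    group than it started.
    """
    if isinstance(hr_g_t, HomeRange):
        cx, cy = hr_g_t.centroid
    elif isinstance(hr_g_t, BaseGeometry):
        cx, cy = hr_g_t.centroid.x, hr_g_t.centroid.y
    else:
        cx, cy = map(float, hr_g_t)
    for z in (overlap_t, overlap_ti):
        g = _geom(z)
        if not isinstance(g, BaseGeometry) or g.is_empty:
            raise ValueError("overlap polygons must be non-empty at both times")
    c_t = _geom(overlap_t).centroid
    c_ti = _geom(overlap_ti).centroid
    d_t = float(np.hypot(c_t.x - cx, c_t.y - cy))
    d_ti = float(np.hypot(c_ti.x - cx, c_ti.y - cy))
    return d_ti - d_t


def select_shift_events(
    panel: pd.DataFrame,
    po_low: float = 0.25,
    po_high: float = 0.45,
    min_size_change: int = 5,
) -> list[ShiftEvent]:
    """All forward period pairs per dyad passing both shift thresholds.

    ``panel`` holds double-entered directed records with columns focal_id,
    neighbour_id, period, po, focal_size, neighbour_size.  Thresholds are
    strict as stated: po_before < 0.25, po_after > 0.45, and the absolute
    net change in the size difference is >= 5.  A dyad-period pair
    qualifies if either direction's PO makes the jump; if both do, the
    direction with the larger increase reports the event.
    """
    required = {"focal_id", "neighbour_id", "period", "po", "focal_size", "neighbour_size"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel is missing columns {sorted(missing)}")
    periods = sorted(panel["period"].unique())
    rec = panel.set_index(["focal_id", "neighbour_id", "period"])

    events: list[ShiftEvent] = []
    pairs = sorted(
        {tuple(sorted(t)) for t in zip(panel["focal_id"], panel["neighbour_id"])}
    )
    for a, b in pairs:
        for i, t in enumerate(periods):
            for u in periods[i + 1 :]:
                best = None
                for f, n in ((a, b), (b, a)):
                    try:
                        row_t = rec.loc[(f, n, t)]
                        row_u = rec.loc[(f, n, u)]
                    except KeyError:
                        continue
                    po_t, po_u = float(row_t["po"]), float(row_u["po"])
                    if not (po_t < po_low and po_u > po_high):
                        continue
                    diff_t = int(row_t["focal_size"]) - int(row_t["neighbour_size"])
                    diff_u = int(row_u["focal_size"]) - int(row_u["neighbour_size"])
                    net = diff_u - diff_t
                    if abs(net) < min_size_change:
                        continue
                    if best is None or (po_u - po_t) > (best.po_after - best.po_before):
                        best = ShiftEvent(
                            pair_id=f"{a}~{b}",
                            focal_id=f,
                            neighbour_id=n,
                            period_t=str(t),
                            period_ti=str(u),
                            po_before=po_t,
                            po_after=po_u,
                            size_change_net=net,
                            larger_becoming=f if net > 0 else n,
                        )
                if best is not None:
                    events.append(best)
    return events


def classify_driver(event: ShiftEvent) -> str:
    """Label the group with the larger |dD| as the driver of the shift.

    Returns "became_larger" when the driver is the group whose relative
    size grew, "became_smaller" otherwise, "indeterminate" on an exact tie.
    """
    db, ds = event.delta_d_bigger, event.delta_d_smaller
    if not (np.isfinite(db) and np.isfinite(ds)):
        raise ValueError("both dD values must be computed before classification")
    if abs(db) == abs(ds):
        event.driver = "indeterminate"
    elif abs(db) > abs(ds):
        event.driver = "became_larger"
    else:
        event.driver = "became_smaller"
    return event.driver


def driver_proportion(
    events: Iterable[ShiftEvent], confidence: float = 0.95
) -> tuple[float, tuple[float, float], int]:
    """Fraction of classified events driven by the larger-becoming group.

    Indeterminate events are excluded; returns (proportion, exact binomial
    CI, number of events used).
    """
    labels = [e.driver for e in events if e.driver and e.driver != "indeterminate"]
    n = len(labels)
    if n == 0:
        raise ValueError("no classifiable shift events")
    k = sum(1 for lab in labels if lab == "became_larger")
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=confidence, method="exact")
    return k / n, (float(ci.low), float(ci.high)), n


def build_directed_records(
    ranges: dict[tuple[str, str], HomeRange],
    sizes: pd.DataFrame,
) -> pd.DataFrame:
    """Double-entered directed overlap table from per-(group, period) ranges.

    ``sizes`` maps group_id x period to size (columns group_id, period,
    size, and optionally season / size_z).  Every ordered pair of groups
    with ranges in a period contributes one row.
    """
    meta = sizes.set_index(["group_id", "period"])
    by_period: dict[str, list[str]] = {}
    for gid, period in ranges:
        by_period.setdefault(period, []).append(gid)
    rows = []
    for period, gids in sorted(by_period.items()):
        for f in sorted(gids):
            for n in sorted(gids):
                if f == n:
                    continue
                res = proportional_overlap(ranges[(f, period)], ranges[(n, period)])
                row = {
                    "focal_id": f,
                    "neighbour_id": n,
                    "dyad_id": f"{min(f, n)}~{max(f, n)}",
                    "period": period,
                    "po": res.po,
                    "ia": res.ia,
                    "hra_focal": res.hra_focal,
                    "focal_size": int(meta.loc[(f, period), "size"]),
                    "neighbour_size": int(meta.loc[(n, period), "size"]),
                }
                if "season" in meta.columns:
                    row["season"] = meta.loc[(f, period), "season"]
                rows.append(row)
    return pd.DataFrame(rows)
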