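"""Constructed range-expansion scenarios for the shift-driver analysis.

Each dyad is an expanding group A sweeping around a static group B: A's
census grows period by period, and its range centre orbits B's range
perimeter (tangential sweep with slow radial closure) in proportion to an
``strength`` dial times the accumulated growth.  Range discs have fixed
radius, so the only expansion channel is the sweep — at strength 0 nothing
moves but placement jitter, and classification of the shift driver is a
coin flip; at high strength the overlap zone slides along B's boundary,
swinging widely relative to A while staying nearly equidistant from B,
and A is classified as the driver.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import Point

from ..dyadic import (
    ShiftEvent,
    classify_driver,
    delta_d,
    overlap_zone,
    select_shift_events,
)
from ..rng import substream

__all__ = ["expansion_scenario", "classify_scenario_events"]

_SIGMA = 280.0
_R95 = np.sqrt(5.991464547107979) * _SIGMA


def expansion_scenario(
    n_dyads: int = 40,
    n_periods: int = 6,
    strength: float = 1.0,
    seed: int = 0,
    jitter_sd: float = 150.0,
    growth_per_period: int = 3,
):
    """Directed PO panel plus range geometries for constructed expansions.

    Returns ``(panel, geoms)``: a double-entered directed overlap table and
    a dict mapping (group_id, period) to the range disc.  Group ``a<k>``
    expands (size 18 upward), ``b<k>`` is static at size 13, so the net
    relative size change after two periods already exceeds the 5-individual
    shift threshold.
    """
    rng = substream(seed, "expansion_scenario")
    rows = []
    geoms = {}
    for k in range(n_dyads):
        a, b = f"a{k:02d}", f"b{k:02d}"
        phi0 = rng.uniform(0, 2 * np.pi)
        sweep_sign = rng.choice([-1.0, 1.0])
        d0 = 1.35 * _R95
        center_b = np.array([0.0, 0.0])
        size_a0, size_b = 18, 13
        for t in range(n_periods):
            growth = growth_per_period * t
            # the radial approach is fixed (every dyad eventually crosses
            # the overlap thresholds); strength dials only the tangential
            # sweep that identifies the expander to the dD measure
            theta = phi0 + sweep_sign * strength * 0.05 * growth
            dist = d0 * float(np.clip(1.0 - 0.035 * growth, 0.45, 1.0))
            center_a = center_b + dist * np.array([np.cos(theta), np.sin(theta)])
            center_a = center_a + rng.normal(0.0, jitter_sd, 2)
            period = f"{t:02d}"
            geoms[(a, period)] = Point(center_a).buffer(_R95, quad_segs=96)
            geoms[(b, period)] = Point(
                center_b + rng.normal(0.0, jitter_sd, 2)
            ).buffer(_R95, quad_segs=96)
            size_a = size_a0 + growth
            for f, n, sf, sn in ((a, b, size_a, size_b), (b, a, size_b, size_a)):
                inter = geoms[(f, period)].intersection(geoms[(n, period)]).area
                rows.append(
                    {
                        "focal_id": f,
                        "neighbour_id": n,
                        "period": period,
                        "po": inter / geoms[(f, period)].area,
                        "focal_size": sf,
                        "neighbour_size": sn,
                    }
                )
    return pd.DataFrame(rows), geoms


def classify_scenario_events(
    panel: pd.DataFrame,
    geoms: dict,
    po_low: float = 0.25,
    po_high: float = 0.45,
    min_size_change: int = 5,
) -> list[ShiftEvent]:
    """Select shift events on the panel and classify their drivers."""
    events = select_shift_events(panel, po_low, po_high, min_size_change)
    classified = []
    for ev in events:
        try:
            zone_t = overlap_zone(
                geoms[(ev.focal_id, ev.period_t)],
                geoms[(ev.neighbour_id, ev.period_t)],
            ).geometry
            zone_u = overlap_zone(
                geoms[(ev.focal_id, ev.period_ti)],
                geoms[(ev.neighbour_id, ev.period_ti)],
            ).geometry
            bigger = ev.larger_becoming
            smaller = ev.neighbour_id if bigger == ev.focal_id else ev.focal_id
            ev.delta_d_bigger = delta_d(geoms[(bigger, ev.period_t)], zone_t, zone_u)
            ev.delta_d_smaller = delta_d(geoms[(smaller, ev.period_t)], zone_t, zone_u)
            classify_driver(ev)
            classified.append(ev)
        except (KeyError, ValueError):
            continue
    return classified
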