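"""Group-size histories: a bounded random walk per group.

Each group's census size performs an integer random walk reflected into
``[size_min, size_max]``, emulating three decades of births, deaths,
immigration and occasional permanent fissions.  Sizes are annual; the dry
and wet season of a year share the same census size.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from ..rng import substream
from ..truth import GenerativeTruth

__all__ = ["gen_demography", "SEASONS"]

SEASONS = ("dry", "wet")  # dry = Jan-Apr, wet = May-Dec


def _reflect(value: float, lo: int, hi: int) -> float:
    # reflect into [lo, hi]; at most a few bounces for realistic steps
    while value < lo or value > hi:
        if value < lo:
            value = 2 * lo - value
        else:
            value = 2 * hi - value
    return value


def gen_demography(
    n_groups: int,
    years: Iterable[int],
    truth: GenerativeTruth | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate per group x year x season census sizes.

    Returns a DataFrame with columns ``group_id, year, season, size,
    size_z``; ``size_z`` is the z-score of size over all emitted records.
    With ``truth.fission_rate > 0``, a fissioning group sheds ~40% of its
    members into a newly labelled daughter group (no spatial inheritance).
    """
    truth = truth or GenerativeTruth()
    truth.validate()
    years = sorted(set(int(y) for y in years))
    if not years:
        raise ValueError("years must be non-empty")
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    rng = substream(seed, "demography")

    lo, hi = truth.size_min, truth.size_max
    groups: dict[str, dict[int, int]] = {}
    sizes_now: dict[str, float] = {}
    for g in range(n_groups):
        gid = f"g{g:02d}"
        start = _reflect(rng.normal(truth.size_init_mean, truth.size_init_sd), lo, hi)
        sizes_now[gid] = start
        groups[gid] = {}

    n_daughters = 0
    for year in years:
        for gid in list(sizes_now):
            step = rng.normal(0.0, truth.size_walk_sd) if truth.size_walk_sd > 0 else 0.0
            sizes_now[gid] = _reflect(sizes_now[gid] + step, lo, hi)
            groups[gid][year] = int(round(sizes_now[gid]))
            if (
                truth.fission_rate > 0
                and sizes_now[gid] > 2 * lo + 4
                and rng.random() < truth.fission_rate
            ):
                daughter = f"g{n_groups + n_daughters:02d}f"
                n_daughters += 1
                shed = max(float(lo), 0.4 * sizes_now[gid])
                sizes_now[gid] = _reflect(sizes_now[gid] - shed, lo, hi)
                sizes_now[daughter] = _reflect(shed, lo, hi)
                groups[daughter] = {year: int(round(sizes_now[daughter]))}
                groups[gid][year] = int(round(sizes_now[gid]))

    rows = [
        {"group_id": gid, "year": year, "season": season, "size": size}
        for gid, history in sorted(groups.items())
        for year, size in sorted(history.items())
        for season in SEASONS
    ]
    df = pd.DataFrame(rows)
    sd = df["size"].std(ddof=1)
    df["size_z"] = 0.0 if not sd > 0 else (df["size"] - df["size"].mean()) / sd
    return df
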