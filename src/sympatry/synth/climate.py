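"""Seasonal water-balance anomaly series (SPEI-like).

Raw anomalies follow an AR(1) process over consecutive season steps,
mimicking the multi-month persistence of ENSO-driven wet/dry spells, then
are z-scored within season so that negative values mean drier than typical
for that season and positive values wetter.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from ..environment import standardize_spei
from ..rng import substream
from ..truth import GenerativeTruth
from .demography import SEASONS

__all__ = ["gen_climate"]


def gen_climate(
    years: Iterable[int],
    truth: GenerativeTruth | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """One row per year x season with ``spei_raw`` and within-season ``spei_z``."""
    truth = truth or GenerativeTruth()
    years = sorted(set(int(y) for y in years))
    if len(years) < 3:
        raise ValueError("need >= 3 years to standardize a seasonal anomaly series")
    rng = substream(seed, "climate")

    phi, sd = truth.spei_ar, truth.spei_innovation_sd
    n_steps = 2 * len(years)
    stationary_sd = sd / np.sqrt(1.0 - phi * phi)
    x = np.empty(n_steps)
    x[0] = rng.normal(0.0, stationary_sd)
    innov = rng.normal(0.0, sd, size=n_steps - 1)
    for t in range(1, n_steps):
        x[t] = phi * x[t - 1] + innov[t - 1]

    rows = [
        {"year": year, "season": season, "spei_raw": x[2 * i + j]}
        for i, year in enumerate(years)
        for j, season in enumerate(SEASONS)
    ]
    return standardize_spei(pd.DataFrame(rows))
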