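"""Focal-follow fruit intake records.

Bite counts are negative-binomial with a log link, an observation-time
offset (seconds the focal individual was in view), a group-size effect that
is modulated by season and by the seasonal climate anomaly, and nested
group- and individual-level intercepts.  The negative binomial is sampled
as a gamma-Poisson mixture, so the dispersion -> infinity limit is exactly
Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..rng import substream
from ..truth import GenerativeTruth

__all__ = ["ForagingConfig", "gen_foraging"]

_AGE_SEX = ("adult_female", "adult_male", "juvenile")


@dataclass
class ForagingConfig:
    individuals_per_group: int = 15
    follows_per_individual_season: int = 2
    seconds_in_view_mean: float = 1200.0   # ~20 min of usable observation
    seconds_in_view_sd: float = 0.4        # lognormal sd on the log scale


def gen_foraging(
    demography: pd.DataFrame,
    climate: pd.DataFrame,
    truth: GenerativeTruth | None = None,
    seed: int = 0,
    config: ForagingConfig | None = None,
) -> pd.DataFrame:
    """One row per focal follow: bites, seconds in view, covariates."""
    truth = truth or GenerativeTruth()
    truth.validate()
    config = config or ForagingConfig()
    rng = substream(seed, "foraging")

    clim = climate.set_index(["year", "season"])["spei_z"]
    groups = sorted(demography["group_id"].unique())
    group_eff = dict(
        zip(groups, rng.normal(0.0, truth.noise.intake_group_sd, len(groups)))
    )
    indiv_ids = {
        g: [f"{g}_i{k:03d}" for k in range(config.individuals_per_group)]
        for g in groups
    }
    indiv_eff = {
        iid: rng.normal(0.0, truth.noise.intake_indiv_sd)
        for ids in indiv_ids.values()
        for iid in ids
    }
    indiv_class = {
        iid: _AGE_SEX[rng.choice(len(_AGE_SEX), p=[0.45, 0.25, 0.30])]
        for ids in indiv_ids.values()
        for iid in ids
    }

    r = truth.noise.nb_dispersion
    rows = []
    for rec in demography.itertuples():
        spei_z = float(clim.loc[(rec.year, rec.season)])
        wet = rec.season == "wet"
        slope = truth.beta_size_intake + spei_z * (
            truth.spei_interactions.intake_wet
            if wet
            else truth.spei_interactions.intake_dry
        )
        base = (
            truth.intake_log_rate
            + (truth.intake_wet if wet else 0.0)
            + slope * float(rec.size_z)
            + group_eff[rec.group_id]
        )
        for iid in indiv_ids[rec.group_id]:
            for _ in range(config.follows_per_individual_season):
                seconds = float(
                    rng.lognormal(
                        np.log(config.seconds_in_view_mean),
                        config.seconds_in_view_sd,
                    )
                )
                mu = np.exp(base + indiv_eff[iid]) * seconds
                lam = rng.gamma(shape=r, scale=mu / r) if np.isfinite(r) else mu
                rows.append(
                    {
                        "individual_id": iid,
                        "group_id": rec.group_id,
                        "year": int(rec.year),
                        "season": rec.season,
                        "size": int(rec.size),
                        "size_z": float(rec.size_z),
                        "spei_z": spei_z,
                        "bites": int(rng.poisson(lam)),
                        "seconds_in_view": seconds,
                        "age_sex_class": indiv_class[iid],
                    }
                )
    return pd.DataFrame(rows)
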