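"""Ground-truth parameters of the synthetic study system.

Every effect estimated downstream (group-level GLMM slopes, social-relations
coefficients, multiple-membership coefficients, variance components) has its
true value recorded here, so parameter recovery can be checked against a
known target.  The whole object round-trips through YAML: a run is fully
reproducible from ``(config, seed)``.

Scales: group-level slopes act on z-scored group size; intake/area/speed
effects are on the log scale, overlap and range-greenness effects on the
logit scale, matching the likelihood families used for inference.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "SpeiInteractions",
    "SRMTruth",
    "MMTruth",
    "NoiseScales",
    "GenerativeTruth",
]


@dataclass
class SpeiInteractions:
    """Season-specific modifiers of the group-size slope per unit SPEI z.

    ``intake_dry`` > 0 makes the (negative) size effect on fruit intake
    steepest in abnormally dry dry-seasons; ``intake_wet`` < 0 makes it
    steepest in abnormally wet wet-seasons; ``ndvi_dry`` > 0 strengthens
    the dry-season size -> range-greenness advantage in wetter-than-usual
    dry seasons.
    """

    intake_dry: float = 0.10
    intake_wet: float = -0.10
    ndvi_dry: float = 0.025


@dataclass
class SRMTruth:
    """Hurdle-beta social-relations model parameters (logit scales).

    The hurdle branch models the probability that a directed overlap is
    exactly zero; the beta branch models the mean of nonzero proportional
    overlap.  ``beta_fn`` < 0 reproduces the focal-size dependence of the
    neighbour-size effect: strong positive for small focal groups, near
    zero or negative for large ones.
    """

    hurdle_intercept: float = -1.0
    hurdle_focal: float = 0.2
    hurdle_neighbour: float = -0.3
    hurdle_fn: float = 0.0
    hurdle_dry: float = 0.5
    beta_intercept: float = -1.0
    beta_focal: float = -0.3
    beta_neighbour: float = 0.25
    beta_fn: float = -0.30
    beta_dry: float = -0.4
    beta_neighbour_dry: float = -0.15
    phi: float = 12.0
    sd_focal: float = 0.4
    sd_neighbour: float = 0.4
    sd_dyad: float = 0.5
    rho_gr: float = 0.3
    rho_dd: float = 0.8

    def validate(self) -> None:
        for name in ("sd_focal", "sd_neighbour", "sd_dyad"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("rho_gr", "rho_dd"):
            rho = getattr(self, name)
            if not -1.0 < rho < 1.0:
                raise ValueError(f"{name} must lie in (-1, 1), got {rho}")
        if self.phi <= 0:
            raise ValueError("phi must be > 0")


@dataclass
class MMTruth:
    """Symmetric multiple-membership encounter model parameters (log scale).

    Response is log encounter rate.  Predictors are standardized before the
    slopes apply.  ``*_dry`` terms are additive dry-season modifiers of the
    corresponding slope; ``b_area_dry`` > 0 encodes more encounters per unit
    shared space in the dry season.
    """

    intercept: float = -6.0
    b_sizediff: float = 0.0
    b_area: float = 0.40
    b_ndvi: float = 0.42
    b_sizediff_dry: float = 0.0
    b_area_dry: float = 0.49
    b_ndvi_dry: float = 0.20
    b_dry: float = 0.6
    sd_dyad: float = 0.4
    sd_group: float = 0.3
    sigma_resid: float = 0.3

    def validate(self) -> None:
        for name in ("sd_dyad", "sd_group", "sigma_resid"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class NoiseScales:
    """Observation-layer noise, one entry per generated response."""

    hra_log_sd: float = 0.15          # biological scatter of log 95% area
    hra_obs_se: float = 0.08          # reported SE of log area (measurement error)
    dpl_obs_se: float = 0.05          # reported SE of log daily path length
    revisit_log_sd: float = 0.10      # scatter of log revisitation rate
    ndvi_phi: float = 150.0           # beta precision of observed range NDVI
    er_log_se: float = 0.10           # reported SE of log encounter rate
    nb_dispersion: float = 1.5        # negative-binomial shape of bite counts
    intake_group_sd: float = 0.20     # group-level intercept sd (log intake)
    intake_indiv_sd: float = 0.25     # individual-level intercept sd

    def validate(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be > 0")


@dataclass
class GenerativeTruth:
    """All true effect sizes and noise scales of the synthetic system."""

    # group-level slopes on z-scored group size
    beta_size_intake: float = -0.20
    beta_size_hra: float = 0.30
    beta_size_ndvi_dry: float = 0.04
    beta_size_revisit: float = -0.15
    spei_interactions: SpeiInteractions = field(default_factory=SpeiInteractions)

    # group-level intercepts / season shifts
    intake_log_rate: float = -5.5     # log bites per second in view, dry season
    intake_wet: float = 0.30          # wet-season shift of log intake
    hra_log_area: float = 14.2        # log m^2 (~150 ha), dry season
    hra_wet: float = 0.15             # wet-season shift of log area
    speed_log: float = -1.4           # log mean travel speed (m/s)
    ndvi_logit_dry: float = -0.2      # logit target zonal NDVI, dry season

    srm: SRMTruth = field(default_factory=SRMTruth)
    mm: MMTruth = field(default_factory=MMTruth)
    noise: NoiseScales = field(default_factory=NoiseScales)

    # demography random walk
    size_min: int = 5
    size_max: int = 40
    size_init_mean: float = 19.0
    size_init_sd: float = 6.0
    size_walk_sd: float = 1.5
    fission_rate: float = 0.0         # per group-year; off by default

    # climate AR(1)
    spei_ar: float = 0.6
    spei_innovation_sd: float = 1.0

    def validate(self) -> None:
        self.srm.validate()
        self.mm.validate()
        self.noise.validate()
        if not 2 <= self.size_min < self.size_max:
            raise ValueError("need 2 <= size_min < size_max")
        if not -1.0 < self.spei_ar < 1.0:
            raise ValueError("spei_ar must lie in (-1, 1)")

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "GenerativeTruth":
        data = dict(data)
        for key, sub in (
            ("spei_interactions", SpeiInteractions),
            ("srm", SRMTruth),
            ("mm", MMTruth),
            ("noise", NoiseScales),
        ):
            if key in data and isinstance(data[key], dict):
                data[key] = sub(**data[key])
        truth = cls(**data)
        truth.validate()
        return truth

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GenerativeTruth":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
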