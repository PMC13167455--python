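"""Symmetric multiple-membership model for dyadic encounter rates.

The response is the log encounter rate of an unordered pair of groups in a
period, Gaussian with a known per-row measurement SE folded into the
residual variance.  Every row loads on the random effects of BOTH member
groups with equal weight, plus a dyad intercept, so the linear predictor —
and hence the whole posterior — is exactly invariant to swapping the two
group labels within any row.  Predictors are the symmetric dyad covariates
(absolute size difference, overlap-zone area, overlap greenness), each
optionally interacted with season.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import (
    ParamLayout,
    PosteriorDraws,
    PosteriorSummary,
    halfnormal_sd_prior,
    laplace_fit,
    normal_prior,
    summarize,
)

__all__ = ["MMSpec", "fit_encounter_mm", "season_slope_contrast", "mm_coef_draws"]

_TERMS = ("size_diff", "area", "ndvi")
_COLS = {"size_diff": "size_diff_z", "area": "overlap_area_z", "ndvi": "overlap_ndvi_z"}


@dataclass
class MMSpec:
    seasonal: bool = False
    response: str = "log_er"
    se: str = "log_er_se"

    def coef_names(self) -> list[str]:
        names = ["intercept", "b_size_diff", "b_area", "b_ndvi"]
        if self.seasonal:
            names += ["b_dry", "b_size_diff_dry", "b_area_dry", "b_ndvi_dry"]
        return names

    def design(self, data: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(data))] + [
            data[_COLS[t]].to_numpy(dtype=float) for t in _TERMS
        ]
        if self.seasonal:
            dry = (data["season"] == "dry").to_numpy(dtype=float)
            cols += [dry] + [data[_COLS[t]].to_numpy(dtype=float) * dry for t in _TERMS]
        return np.column_stack(cols)


def fit_encounter_mm(
    spec: MMSpec,
    records: pd.DataFrame,
    seed: int = 0,
    n_draws: int = 2000,
) -> PosteriorDraws:
    """Fit the multiple-membership encounter model on pair-period rows.

    ``records`` needs group_1, group_2, dyad_id, season, the standardized
    covariate columns, the log response and its per-row SE.
    """
    records = records.reset_index(drop=True)
    X = spec.design(records)
    n, p = X.shape
    y = records[spec.response].to_numpy(dtype=float)
    se = records[spec.se].to_numpy(dtype=float)
    if np.any(se <= 0):
        raise ValueError("log-response SEs must be positive")

    groups = sorted(set(records["group_1"]) | set(records["group_2"]))
    gidx = {g: i for i, g in enumerate(groups)}
    J = len(groups)
    i1 = records["group_1"].map(gidx).to_numpy()
    i2 = records["group_2"].map(gidx).to_numpy()
    dyads = sorted(records["dyad_id"].unique())
    didx = {d: i for i, d in enumerate(dyads)}
    D = len(dyads)
    di = records["dyad_id"].map(didx).to_numpy()

    # non-centered random effects: effect = exp(log_sd) * z, z ~ N(0, 1)
    layout = ParamLayout()
    layout.add("beta", p)
    layout.add("z_group", J)
    layout.add("z_dyad", D)
    layout.add("log_sd_group", 1)
    layout.add("log_sd_dyad", 1)
    layout.add("log_sigma", 1)

    def nlp_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        grad = np.zeros_like(theta)
        beta = layout.get(theta, "beta")
        sd_g = float(np.exp(theta[layout.slice("log_sd_group")][0]))
        sd_d = float(np.exp(theta[layout.slice("log_sd_dyad")][0]))
        ug = sd_g * layout.get(theta, "z_group")
        ud = sd_d * layout.get(theta, "z_dyad")
        sigma2 = float(np.exp(2 * theta[layout.slice("log_sigma")][0]))
        # equal-weight multiple membership: both groups' effects enter; the
        # pair sum is grouped first so label order cannot change the result
        eta = X @ beta + (ug[i1] + ug[i2]) + ud[di]
        v = sigma2 + se**2
        resid = y - eta
        nlp = float(np.sum(0.5 * np.log(2 * np.pi * v) + 0.5 * resid**2 / v))
        deta = -resid / v
        grad[layout.slice("beta")] += X.T @ deta
        agg_g = np.bincount(i1, weights=deta, minlength=J) + np.bincount(
            i2, weights=deta, minlength=J
        )
        agg_d = np.bincount(di, weights=deta, minlength=D)
        grad[layout.slice("z_group")] += sd_g * agg_g
        grad[layout.slice("z_dyad")] += sd_d * agg_d
        grad[layout.slice("log_sd_group")] += float(np.dot(agg_g, ug))
        grad[layout.slice("log_sd_dyad")] += float(np.dot(agg_d, ud))
        dv = 0.5 / v - 0.5 * resid**2 / v**2
        grad[layout.slice("log_sigma")] += float(np.sum(dv)) * 2 * sigma2

        bsl = layout.slice("beta")
        bv = theta[bsl]
        psd = np.ones(p)
        psd[0] = 10.0  # wide prior on the log-rate intercept
        grad[bsl] += bv / psd**2
        nlp += float(0.5 * np.sum((bv / psd) ** 2))
        nlp += normal_prior(theta, grad, layout.slice("z_group"))
        nlp += normal_prior(theta, grad, layout.slice("z_dyad"))
        nlp += halfnormal_sd_prior(theta, grad, layout.slice("log_sd_group"))
        nlp += halfnormal_sd_prior(theta, grad, layout.slice("log_sd_dyad"))
        nlp += normal_prior(theta, grad, layout.slice("log_sigma"))
        return nlp, grad

    x0 = np.zeros(layout.size)
    x0[0] = y.mean()
    x0[layout.slice("log_sd_group")] = np.log(0.3)
    x0[layout.slice("log_sd_dyad")] = np.log(0.3)
    x0[layout.slice("log_sigma")] = np.log(max(float(y.std()), 1e-3))

    return laplace_fit(
        nlp_grad,
        layout,
        x0,
        seed=seed,
        n_draws=n_draws,
        meta={"coef_names": spec.coef_names(), "n_obs": n},
    )


def mm_coef_draws(fit: PosteriorDraws, name: str) -> np.ndarray:
    names = fit.meta["coef_names"]
    if name not in names:
        raise KeyError(f"{name!r} not among {names}")
    return fit["beta"][:, names.index(name)]


def season_slope_contrast(fit: PosteriorDraws, term: str) -> PosteriorSummary:
    """Wet-minus-dry posterior contrast of a named symmetric predictor."""
    if term not in _TERMS:
        raise ValueError(f"term must be one of {_TERMS}")
    # wet slope = b_term; dry slope = b_term + b_term_dry
    diff = -mm_coef_draws(fit, f"b_{term}_dry")
    return summarize(diff, label=f"wet_minus_dry[{term}]")
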