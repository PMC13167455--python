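"""Group-level Bayesian GLMMs.

One fitting routine covers the family mapping used throughout: negative
binomial with a log link and an observation-time offset for bite counts,
gamma with a log link for areas / path lengths / revisitation rates, beta
with a logit link for range greenness, and Gaussian for log-scale responses
with known per-row measurement error.  Seasonal models interact group size
with season; the climate-extended models add the three-way
size x season x SPEI interaction.  Measurement error on a gamma response is
marginalized analytically by matching the exact log-gamma moments (the log
response is Gaussian with mean psi(k) - log k + log mu and variance
psi_1(k) plus the known squared SE); Gaussian measurement error is folded
into the residual variance the same way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, expit, gammaln, polygamma

from .engine import (
    ParamLayout,
    PosteriorDraws,
    PosteriorSummary,
    halfnormal_sd_prior,
    laplace_fit,
    normal_prior,
    summarize,
)

__all__ = [
    "GroupModelSpec",
    "fit_group_glmm",
    "coef_draws",
    "size_slope_draws",
    "marginal_slope",
    "seasonal_contrast",
]

_FAMILIES = ("negative_binomial", "gamma", "beta", "gaussian")
BETA_EPS = 1e-6


@dataclass
class GroupModelSpec:
    """What to regress on what, and with which likelihood."""

    response: str
    family: str
    offset: str | None = None          # exposure column, logged internally
    me_se: str | None = None           # known per-row SE on the link scale
    seasonal: bool = False             # size x season interaction
    spei: bool = False                 # three-way size x season x SPEI
    group: str = "group_id"
    extra_varying: str | None = None   # e.g. individual_id or year

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.spei and not self.seasonal:
            raise ValueError("the three-way SPEI term requires a seasonal model")

    def coef_names(self) -> list[str]:
        names = ["intercept", "b_size"]
        if self.seasonal:
            names += ["b_wet", "b_size_wet"]
        if self.spei:
            names += ["b_spei", "b_spei_wet", "b_size_spei", "b_size_spei_wet"]
        return names

    def design(self, data: pd.DataFrame) -> np.ndarray:
        size = data["size_z"].to_numpy(dtype=float)
        cols = [np.ones(len(data)), size]
        if self.seasonal:
            wet = (data["season"] == "wet").to_numpy(dtype=float)
            cols += [wet, size * wet]
        if self.spei:
            spei = data["spei_z"].to_numpy(dtype=float)
            cols += [spei, spei * wet, size * spei, size * spei * wet]
        return np.column_stack(cols)


def _codes(values: pd.Series) -> tuple[np.ndarray, int]:
    cat = pd.Categorical(values)
    return cat.codes.astype(int), len(cat.categories)


def fit_group_glmm(
    spec: GroupModelSpec,
    data: pd.DataFrame,
    seed: int = 0,
    n_draws: int = 2000,
) -> PosteriorDraws:
    """Fit the model and return posterior draws for all parameters."""
    data = data.reset_index(drop=True)
    X = spec.design(data)
    n, p = X.shape
    y = data[spec.response].to_numpy(dtype=float)
    off = (
        np.log(data[spec.offset].to_numpy(dtype=float))
        if spec.offset
        else np.zeros(n)
    )
    gi, J = _codes(data[spec.group])
    ei, K = (_codes(data[spec.extra_varying]) if spec.extra_varying else (None, 0))

    se = None
    if spec.me_se:
        se = data[spec.me_se].to_numpy(dtype=float)
        if np.any(se <= 0):
            raise ValueError("measurement-error SEs must be positive")

    n_nudged = 0
    if spec.family == "beta":
        lo, hi = y.min(), y.max()
        if lo < 0 or hi > 1:
            raise ValueError("beta responses must lie in [0, 1]")
        n_nudged = int(np.sum((y <= 0) | (y >= 1)))
        y = np.clip(y, BETA_EPS, 1 - BETA_EPS)
        logy, log1my = np.log(y), np.log1p(-y)
    if spec.family in ("gamma", "negative_binomial") and np.any(y < 0):
        raise ValueError("response must be non-negative for this family")

    gamma_me = spec.family == "gamma" and se is not None

    # random effects are non-centered: effect = exp(log_sd) * z, z ~ N(0, 1),
    # which keeps the joint posterior mode away from the sd -> 0 funnel
    layout = ParamLayout()
    layout.add("beta", p)
    layout.add("z_group", J)
    if K:
        layout.add("z_extra", K)
    layout.add("log_sd_group", 1)
    if K:
        layout.add("log_sd_extra", 1)
    layout.add("aux", 1)  # log dispersion / shape / precision / sigma

    w = np.log(np.maximum(y, 1e-12))  # link-scale observed response

    def nlp_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        grad = np.zeros_like(theta)
        beta = layout.get(theta, "beta")
        sd_g = float(np.exp(theta[layout.slice("log_sd_group")][0]))
        u_g = sd_g * layout.get(theta, "z_group")
        eta = X @ beta + off + u_g[gi]
        if K:
            sd_e = float(np.exp(theta[layout.slice("log_sd_extra")][0]))
            u_e = sd_e * layout.get(theta, "z_extra")
            eta = eta + u_e[ei]
        eta = np.clip(eta, -40.0, 40.0)
        aux_sl = layout.slice("aux")
        aux = float(theta[aux_sl][0])

        if spec.family == "negative_binomial":
            r = np.exp(aux)
            mu = np.exp(eta)
            ll = (
                gammaln(y + r)
                - gammaln(r)
                - gammaln(y + 1)
                + r * (aux - np.log(r + mu))
                + y * (eta - np.log(r + mu))
            )
            deta = -(y - (y + r) * mu / (r + mu))
            daux = -r * np.sum(
                digamma(y + r)
                - digamma(r)
                + aux
                + 1.0
                - np.log(r + mu)
                - (y + r) / (r + mu)
            )
        elif spec.family == "gamma" and not gamma_me:
            k = np.exp(aux)
            ll = k * aux - gammaln(k) + (k - 1) * w - k * eta - k * np.exp(w - eta)
            deta = -(-k + k * np.exp(w - eta))
            daux = -k * np.sum(aux + 1 - digamma(k) + w - eta - np.exp(w - eta))
        elif gamma_me:
            # measurement error on the log response: the log of a gamma
            # variate has exact mean psi(k) - log k + eta and variance
            # psi_1(k); treating it as Gaussian marginalizes the latent
            # true response analytically
            k = np.exp(aux)
            shift = digamma(k) - aux
            v = se**2 + polygamma(1, k)
            resid = w - eta - shift
            ll = -0.5 * np.log(2 * np.pi * v) - 0.5 * resid**2 / v
            deta = -resid / v
            dshift_dlk = k * polygamma(1, k) - 1.0
            dv_dlk = k * polygamma(2, k)
            dll_dlk = (resid / v) * dshift_dlk + (
                -0.5 / v + 0.5 * resid**2 / v**2
            ) * dv_dlk
            daux = -float(np.sum(dll_dlk))
        elif spec.family == "beta":
            phi = np.exp(aux)
            mu = expit(eta)
            a, b = mu * phi, (1 - mu) * phi
            ll = (
                gammaln(phi)
                - gammaln(a)
                - gammaln(b)
                + (a - 1) * logy
                + (b - 1) * log1my
            )
            dmu = phi * (-digamma(a) + digamma(b) + logy - log1my)
            deta = -dmu * mu * (1 - mu)
            daux = -phi * np.sum(
                digamma(phi) - mu * digamma(a) - (1 - mu) * digamma(b)
                + mu * logy + (1 - mu) * log1my
            )
        else:  # gaussian, optional known SE folded into the variance
            sigma2 = np.exp(2 * aux)
            v = sigma2 + (se**2 if se is not None else 0.0)
            ll = -0.5 * np.log(2 * np.pi * v) - 0.5 * (y - eta) ** 2 / v
            deta = -(y - eta) / v
            dv = -0.5 / v + 0.5 * (y - eta) ** 2 / v**2
            daux = -np.sum(dv) * 2 * sigma2

        nlp = -float(ll.sum())
        grad[layout.slice("beta")] += X.T @ deta
        agg_g = np.bincount(gi, weights=deta, minlength=J)
        grad[layout.slice("z_group")] += sd_g * agg_g
        grad[layout.slice("log_sd_group")] += float(np.dot(agg_g, u_g))
        if K:
            agg_e = np.bincount(ei, weights=deta, minlength=K)
            grad[layout.slice("z_extra")] += sd_e * agg_e
            grad[layout.slice("log_sd_extra")] += float(np.dot(agg_e, u_e))
        grad[aux_sl] += daux

        # weakly regularizing: N(0,1) on standardized-scale slopes but a
        # wide N(0,10) prior on the intercept, whose scale is the link scale
        bsl = layout.slice("beta")
        bv = theta[bsl]
        psd = np.ones(p)
        psd[0] = 10.0
        grad[bsl] += bv / psd**2
        nlp += float(0.5 * np.sum((bv / psd) ** 2))
        nlp += normal_prior(theta, grad, layout.slice("z_group"))
        nlp += halfnormal_sd_prior(theta, grad, layout.slice("log_sd_group"))
        if K:
            nlp += normal_prior(theta, grad, layout.slice("z_extra"))
            nlp += halfnormal_sd_prior(theta, grad, layout.slice("log_sd_extra"))
        nlp += normal_prior(theta, grad, aux_sl)
        return nlp, grad

    # initialize the fixed effects from a link-scale least-squares fit so
    # the optimizer starts near the likelihood ridge
    x0 = np.zeros(layout.size)
    if spec.family == "negative_binomial":
        target = np.log((y + 0.5) / np.exp(off))
    elif spec.family == "gamma":
        target = w
    elif spec.family == "beta":
        target = np.log(y / (1 - y))
    else:
        target = y
    beta0, *_ = np.linalg.lstsq(X, target, rcond=None)
    x0[layout.slice("beta")] = beta0
    resid_var = float(np.var(target - X @ beta0))
    if spec.family == "gamma":
        x0[layout.slice("aux")] = -np.log(max(resid_var, 1e-4))
    elif spec.family == "beta":
        x0[layout.slice("aux")] = np.log(10.0)
    elif spec.family == "gaussian":
        x0[layout.slice("aux")] = 0.5 * np.log(max(resid_var, 1e-6))
    x0[layout.slice("log_sd_group")] = np.log(0.3)
    if K:
        x0[layout.slice("log_sd_extra")] = np.log(0.3)

    fit = laplace_fit(
        nlp_grad,
        layout,
        x0,
        seed=seed,
        n_draws=n_draws,
        meta={
            "coef_names": spec.coef_names(),
            "family": spec.family,
            "n_nudged": n_nudged,
            "n_obs": n,
        },
    )
    return fit


def coef_draws(fit: PosteriorDraws, name: str) -> np.ndarray:
    """Posterior draws of a named fixed-effect coefficient."""
    names = fit.meta["coef_names"]
    if name not in names:
        raise KeyError(f"{name!r} not among {names}")
    return fit["beta"][:, names.index(name)]


def size_slope_draws(
    fit: PosteriorDraws, season: str = "annual", spei: float = 0.0
) -> np.ndarray:
    """Per-draw group-size slope at a season and SPEI value."""
    names = fit.meta["coef_names"]
    slope = coef_draws(fit, "b_size").copy()
    if season == "wet":
        if "b_size_wet" not in names:
            raise ValueError("model has no seasonal terms")
        slope = slope + coef_draws(fit, "b_size_wet")
    if "b_size_spei" in names and spei != 0.0:
        slope = slope + spei * coef_draws(fit, "b_size_spei")
        if season == "wet":
            slope = slope + spei * coef_draws(fit, "b_size_spei_wet")
    return slope


def marginal_slope(
    fit: PosteriorDraws, season: str = "annual", spei: float = 0.0
) -> PosteriorSummary:
    """Posterior summary of the size slope conditional on season and SPEI."""
    return summarize(
        size_slope_draws(fit, season, spei),
        label=f"size_slope[{season}, spei={spei:g}]",
    )


def seasonal_contrast(
    fit: PosteriorDraws, estimand: str = "size_slope", spei: float = 0.0
) -> PosteriorSummary:
    """Wet-minus-dry posterior contrast of the named estimand."""
    if estimand == "size_slope":
        diff = size_slope_draws(fit, "wet", spei) - size_slope_draws(fit, "dry", spei)
    elif estimand == "level":
        diff = coef_draws(fit, "b_wet").copy()
        if "b_spei_wet" in fit.meta["coef_names"] and spei != 0.0:
            diff = diff + spei * coef_draws(fit, "b_spei_wet")
    else:
        raise ValueError(f"unknown estimand {estimand!r}")
    return summarize(diff, label=f"wet_minus_dry[{estimand}]")
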