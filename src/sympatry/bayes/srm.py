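"""Hurdle-beta social relations model for directed home-range overlap.

Directed proportional overlap PO is zero-augmented: a Bernoulli hurdle
gives the probability that a focal range shares no area with the
neighbour, and a beta distribution describes the degree of overlap when
present.  Variance partitions into a per-group focal ("giving") effect g, a
per-group neighbour ("receiving") effect r, correlated within group, and a
pair of directed dyad effects (d_ij, d_ji) correlated within dyad.  Both
directions of every dyad enter as separate rows.  By default the varying
effects are shared between the hurdle and beta branches, with
branch-specific fixed effects; ``share_varying=False`` gives each branch
its own effects.

The correlated effect pairs use a non-centered (Cholesky) parameterization
— raw standard-normal coordinates scaled by the sds and rotated by the
correlation — which keeps the joint posterior mode away from the
degenerate ridge at |rho| = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betaln, digamma, expit, gammaln

from .engine import (
    ParamLayout,
    PosteriorDraws,
    PosteriorSummary,
    halfnormal_sd_prior,
    laplace_fit,
    lkj2_prior,
    normal_prior,
    summarize,
)

__all__ = [
    "SRMSpec",
    "hurdle_beta_loglik",
    "fit_srm",
    "conditional_neighbour_slope",
    "neighbour_slope_draws",
    "rho_draws",
]

_RHO_MAX = 0.999999


def hurdle_beta_loglik(po: float, theta: float, mu: float, phi: float) -> float:
    """Log density of the zero-augmented beta at a single value.

    ``theta`` is the probability of exactly zero; positive values follow a
    beta with mean ``mu`` and precision ``phi``.  A value of exactly 1 is
    shrunk by the documented epsilon (1e-12).
    """
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must lie in (0, 1)")
    if not 0.0 < mu < 1.0:
        raise ValueError("mu must lie in (0, 1)")
    if phi <= 0:
        raise ValueError("phi must be positive")
    if not 0.0 <= po <= 1.0:
        raise ValueError("po must lie in [0, 1]")
    if po == 0.0:
        return float(np.log(theta))
    if po == 1.0:
        po = 1.0 - 1e-12
    a, b = mu * phi, (1.0 - mu) * phi
    return float(
        np.log1p(-theta)
        + (a - 1) * np.log(po)
        + (b - 1) * np.log1p(-po)
        - betaln(a, b)
    )


@dataclass
class SRMSpec:
    seasonal: bool = False
    share_varying: bool = True

    def coef_names(self) -> list[str]:
        names = ["intercept", "b_focal", "b_neighbour", "b_fn"]
        if self.seasonal:
            names += ["b_dry", "b_focal_dry", "b_neighbour_dry"]
        return names

    def design(self, fz: np.ndarray, nz: np.ndarray, dry: np.ndarray) -> np.ndarray:
        cols = [np.ones_like(fz), fz, nz, fz * nz]
        if self.seasonal:
            cols += [dry, fz * dry, nz * dry]
        return np.column_stack(cols)


def _validate_double_entry(records: pd.DataFrame) -> None:
    keyed = set(zip(records["focal_id"], records["neighbour_id"], records["period"]))
    for f, n, t in keyed:
        if (n, f, t) not in keyed:
            raise ValueError(
                f"double-entry violation: ({n!r}, {f!r}, {t!r}) direction missing"
            )


def fit_srm(
    spec: SRMSpec,
    records: pd.DataFrame,
    seed: int = 0,
    n_draws: int = 2000,
    size_mean: float | None = None,
    size_sd: float | None = None,
    refine_hypers: bool = True,
) -> PosteriorDraws:
    """Fit the hurdle-beta SRM on double-entered directed dyad records.

    ``records`` needs columns focal_id, neighbour_id, period, season, po,
    focal_size, neighbour_size (and optionally precomputed *_size_z).  The
    size z-scaling is stored with the fit for conditional-slope evaluation.
    With ``refine_hypers`` (default, shared-varying structure only) the six
    hyperparameters are re-inferred from their latent-integrated marginal
    posterior via nested Laplace, which locates variance and correlation
    parameters far better than the joint mode.
    """
    records = records.reset_index(drop=True)
    _validate_double_entry(records)

    sizes = records["focal_size"].to_numpy(dtype=float)
    size_mean = float(sizes.mean()) if size_mean is None else float(size_mean)
    size_sd = float(sizes.std(ddof=1)) if size_sd is None else float(size_sd)
    if "focal_size_z" in records:
        fz = records["focal_size_z"].to_numpy(dtype=float)
        nz = records["neighbour_size_z"].to_numpy(dtype=float)
    else:
        fz = (sizes - size_mean) / size_sd
        nz = (records["neighbour_size"].to_numpy(dtype=float) - size_mean) / size_sd
    dry = (records["season"] == "dry").to_numpy(dtype=float)
    X = spec.design(fz, nz, dry)
    n, p = X.shape

    po = records["po"].to_numpy(dtype=float)
    if np.any((po < 0) | (po > 1)):
        raise ValueError("po must lie in [0, 1]")
    zero = po == 0.0
    po = np.where(po >= 1.0, 1.0 - 1e-9, po)
    logy = np.where(zero, 0.0, np.log(np.maximum(po, 1e-300)))
    log1my = np.where(zero, 0.0, np.log1p(-po))

    groups = sorted(set(records["focal_id"]) | set(records["neighbour_id"]))
    g_index = {g: i for i, g in enumerate(groups)}
    J = len(groups)
    fi = records["focal_id"].map(g_index).to_numpy()
    ni = records["neighbour_id"].map(g_index).to_numpy()

    dyads = sorted(
        {tuple(sorted(t)) for t in zip(records["focal_id"], records["neighbour_id"])}
    )
    d_index = {d: i for i, d in enumerate(dyads)}
    D = len(dyads)
    di = np.array(
        [
            d_index[tuple(sorted((f, m)))]
            for f, m in zip(records["focal_id"], records["neighbour_id"])
        ]
    )
    # direction 0 is the (min, max) ordering, 1 the reverse
    dcol = (
        records["focal_id"].to_numpy() > records["neighbour_id"].to_numpy()
    ).astype(int)
    fwd = dcol == 0

    branches = ["shared"] if spec.share_varying else ["h", "b"]
    layout = ParamLayout()
    layout.add("hurdle", p)
    layout.add("beta", p)
    for br in branches:
        layout.add(f"z_gr_{br}", (J, 2))
        layout.add(f"z_d_{br}", (D, 2))
    for br in branches:
        layout.add(f"log_sd_g_{br}", 1)
        layout.add(f"log_sd_r_{br}", 1)
        layout.add(f"log_sd_d_{br}", 1)
        layout.add(f"atanh_rho_gr_{br}", 1)
        layout.add(f"atanh_rho_dd_{br}", 1)
    layout.add("log_phi", 1)

    def _hypers(theta: np.ndarray, br: str):
        s_g = float(np.exp(theta[layout.slice(f"log_sd_g_{br}")][0]))
        s_r = float(np.exp(theta[layout.slice(f"log_sd_r_{br}")][0]))
        s_d = float(np.exp(theta[layout.slice(f"log_sd_d_{br}")][0]))
        rho_gr = float(
            np.clip(
                np.tanh(theta[layout.slice(f"atanh_rho_gr_{br}")][0]),
                -_RHO_MAX,
                _RHO_MAX,
            )
        )
        rho_dd = float(
            np.clip(
                np.tanh(theta[layout.slice(f"atanh_rho_dd_{br}")][0]),
                -_RHO_MAX,
                _RHO_MAX,
            )
        )
        return s_g, s_r, s_d, rho_gr, rho_dd

    def branch_effects(theta: np.ndarray, br: str):
        """Non-centered construction of g, r and directed dyad effects."""
        z_gr = layout.get(theta, f"z_gr_{br}")
        z_d = layout.get(theta, f"z_d_{br}")
        s_g, s_r, s_d, rho_gr, rho_dd = _hypers(theta, br)
        w_gr = np.sqrt(1.0 - rho_gr**2)
        w_dd = np.sqrt(1.0 - rho_dd**2)
        g = s_g * z_gr[:, 0]
        r = s_r * (rho_gr * z_gr[:, 0] + w_gr * z_gr[:, 1])
        d0 = s_d * z_d[:, 0]
        d1 = s_d * (rho_dd * z_d[:, 0] + w_dd * z_d[:, 1])
        re = g[fi] + r[ni] + np.where(fwd, d0[di], d1[di])
        cache = (z_gr, z_d, s_g, s_r, s_d, rho_gr, rho_dd, w_gr, w_dd, g, r, d0, d1)
        return re, cache

    def scatter_effects(grad: np.ndarray, br: str, deta: np.ndarray, cache) -> None:
        (z_gr, z_d, s_g, s_r, s_d, rho_gr, rho_dd, w_gr, w_dd, g, r, d0, d1) = cache
        dg = np.bincount(fi, weights=deta, minlength=J)
        dr = np.bincount(ni, weights=deta, minlength=J)
        dd0 = np.bincount(di[fwd], weights=deta[fwd], minlength=D)
        dd1 = np.bincount(di[~fwd], weights=deta[~fwd], minlength=D)

        gz = np.zeros((J, 2))
        gz[:, 0] = s_g * dg + s_r * rho_gr * dr
        gz[:, 1] = s_r * w_gr * dr
        grad[layout.slice(f"z_gr_{br}")] += gz.ravel()

        dz = np.zeros((D, 2))
        dz[:, 0] = s_d * dd0 + s_d * rho_dd * dd1
        dz[:, 1] = s_d * w_dd * dd1
        grad[layout.slice(f"z_d_{br}")] += dz.ravel()

        grad[layout.slice(f"log_sd_g_{br}")] += float(np.sum(dg * g))
        grad[layout.slice(f"log_sd_r_{br}")] += float(np.sum(dr * r))
        grad[layout.slice(f"log_sd_d_{br}")] += float(np.sum(dd0 * d0 + dd1 * d1))
        # d r / d rho = s_r (z1 - rho z2 / w); chain by drho/dc = 1 - rho^2
        grad[layout.slice(f"atanh_rho_gr_{br}")] += float(
            np.sum(dr * s_r * (z_gr[:, 0] - rho_gr * z_gr[:, 1] / w_gr))
            * (1.0 - rho_gr**2)
        )
        grad[layout.slice(f"atanh_rho_dd_{br}")] += float(
            np.sum(dd1 * s_d * (z_d[:, 0] - rho_dd * z_d[:, 1] / w_dd))
            * (1.0 - rho_dd**2)
        )

    def nlp_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        grad = np.zeros_like(theta)
        br_h = "shared" if spec.share_varying else "h"
        br_b = "shared" if spec.share_varying else "b"
        re_h, cache_h = branch_effects(theta, br_h)
        re_b, cache_b = (
            (re_h, cache_h) if spec.share_varying else branch_effects(theta, br_b)
        )
        eta_h = np.clip(X @ layout.get(theta, "hurdle") + re_h, -40, 40)
        eta_b = np.clip(X @ layout.get(theta, "beta") + re_b, -40, 40)
        phi = float(np.exp(theta[layout.slice("log_phi")][0]))

        theta_h = expit(eta_h)
        mu = expit(eta_b)
        a, b = mu * phi, (1 - mu) * phi

        ll = np.where(
            zero,
            np.log(np.maximum(theta_h, 1e-300)),
            np.log(np.maximum(1 - theta_h, 1e-300)),
        )
        nz_mask = ~zero
        ll_beta = np.zeros(n)
        ll_beta[nz_mask] = (
            gammaln(phi)
            - gammaln(a[nz_mask])
            - gammaln(b[nz_mask])
            + (a[nz_mask] - 1) * logy[nz_mask]
            + (b[nz_mask] - 1) * log1my[nz_mask]
        )
        nlp = -float((ll + ll_beta).sum())

        deta_h = -np.where(zero, 1 - theta_h, -theta_h)
        dmu = np.zeros(n)
        dmu[nz_mask] = phi * (
            -digamma(a[nz_mask]) + digamma(b[nz_mask]) + logy[nz_mask] - log1my[nz_mask]
        )
        deta_b = -dmu * mu * (1 - mu)
        dphi = (
            -np.sum(
                phi
                * (
                    digamma(phi)
                    - mu[nz_mask] * digamma(a[nz_mask])
                    - (1 - mu[nz_mask]) * digamma(b[nz_mask])
                    + mu[nz_mask] * logy[nz_mask]
                    + (1 - mu[nz_mask]) * log1my[nz_mask]
                )
            )
            if nz_mask.any()
            else 0.0
        )

        grad[layout.slice("hurdle")] += X.T @ deta_h
        grad[layout.slice("beta")] += X.T @ deta_b
        if spec.share_varying:
            scatter_effects(grad, "shared", deta_h + deta_b, cache_h)
        else:
            scatter_effects(grad, "h", deta_h, cache_h)
            scatter_effects(grad, "b", deta_b, cache_b)
        grad[layout.slice("log_phi")] += dphi

        for br_name in ("hurdle", "beta"):
            bsl = layout.slice(br_name)
            bv = theta[bsl]
            psd = np.ones(p)
            psd[0] = 10.0  # wide prior on the branch intercept
            grad[bsl] += bv / psd**2
            nlp += float(0.5 * np.sum((bv / psd) ** 2))
        nlp += normal_prior(theta, grad, layout.slice("log_phi"))
        for br in branches:
            nlp += normal_prior(theta, grad, layout.slice(f"z_gr_{br}"))
            nlp += normal_prior(theta, grad, layout.slice(f"z_d_{br}"))
            for nm in (f"log_sd_g_{br}", f"log_sd_r_{br}", f"log_sd_d_{br}"):
                nlp += halfnormal_sd_prior(theta, grad, layout.slice(nm))
            for nm in (f"atanh_rho_gr_{br}", f"atanh_rho_dd_{br}"):
                nlp += lkj2_prior(theta, grad, layout.slice(nm))
        return nlp, grad

    x0 = np.zeros(layout.size)
    zero_rate = float(zero.mean())
    x0[layout.slice("hurdle")][0] = float(
        np.log((zero_rate + 1e-3) / (1 - zero_rate + 1e-3))
    )
    mean_po = float(po[~zero].mean()) if (~zero).any() else 0.5
    x0[layout.slice("beta")][0] = float(np.log(mean_po / (1 - mean_po)))
    for br in branches:
        for nm in (f"log_sd_g_{br}", f"log_sd_r_{br}", f"log_sd_d_{br}"):
            x0[layout.slice(nm)] = np.log(0.3)
    x0[layout.slice("log_phi")] = np.log(8.0)

    from collections import Counter

    dyad_members = Counter(g for d in dyads for g in d)
    weak = [g for g in groups if dyad_members[g] < 2]
    if weak:
        import warnings

        warnings.warn(
            f"groups appearing in < 2 dyads have weakly identified effects: {weak}",
            stacklevel=2,
        )

    meta = {
        "coef_names": spec.coef_names(),
        "size_mean": size_mean,
        "size_sd": size_sd,
        "n_zero": int(zero.sum()),
        "n_obs": n,
        "share_varying": spec.share_varying,
    }
    stage1 = laplace_fit(nlp_grad, layout, x0, seed=seed, n_draws=n_draws, meta=meta)
    if not (refine_hypers and spec.share_varying):
        return stage1

    # nested-Laplace refinement of the hyperparameters
    from .srm_marginal import marginal_srm_fit

    tm = stage1.theta_map
    _, cache = branch_effects(tm, "shared")
    (_, _, _, _, _, _, _, _, _, g, r, d0, d1) = cache
    u0 = np.concatenate(
        [
            layout.get(tm, "hurdle"),
            layout.get(tm, "beta"),
            g,
            r,
            np.column_stack([d0, d1]).ravel(),
        ]
    )
    eta0 = np.array(
        [
            tm[layout.slice("log_sd_g_shared")][0],
            tm[layout.slice("log_sd_r_shared")][0],
            tm[layout.slice("log_sd_d_shared")][0],
            tm[layout.slice("atanh_rho_gr_shared")][0],
            tm[layout.slice("atanh_rho_dd_shared")][0],
            tm[layout.slice("log_phi")][0],
        ]
    )
    refined = marginal_srm_fit(
        X, fi, ni, di * 2 + dcol, zero, logy, log1my, J, D,
        eta0, u0, seed=seed, n_draws=n_draws, meta=meta,
    )
    refined.meta["stage1_converged"] = stage1.converged
    return refined


def _branch_coef(fit: PosteriorDraws, branch: str, name: str) -> np.ndarray:
    names = fit.meta["coef_names"]
    if name not in names:
        raise KeyError(f"{name!r} not among {names}")
    return fit[branch][:, names.index(name)]


def neighbour_slope_draws(
    fit: PosteriorDraws,
    focal_size: float,
    branch: str = "beta",
    season: str | None = None,
) -> np.ndarray:
    """Per-draw neighbour-size slope at a focal group size (head count)."""
    z = (focal_size - fit.meta["size_mean"]) / fit.meta["size_sd"]
    slope = _branch_coef(fit, branch, "b_neighbour") + z * _branch_coef(
        fit, branch, "b_fn"
    )
    if season == "dry":
        slope = slope + _branch_coef(fit, branch, "b_neighbour_dry")
    return slope


def conditional_neighbour_slope(
    fit: PosteriorDraws,
    focal_sizes: tuple[float, ...] = (8, 21, 35),
    branch: str = "beta",
    season: str | None = None,
) -> list[PosteriorSummary]:
    """Neighbour-size slope summaries at representative focal sizes."""
    return [
        summarize(
            neighbour_slope_draws(fit, s, branch, season),
            label=f"neighbour_slope[focal={s:g}]",
        )
        for s in focal_sizes
    ]


def rho_draws(
    fit: PosteriorDraws, which: str = "dd", branch: str | None = None
) -> np.ndarray:
    """Posterior draws of a correlation on the natural scale."""
    br = branch or ("shared" if fit.meta.get("share_varying", True) else "b")
    return np.tanh(fit[f"atanh_rho_{which}_{br}"][:, 0])
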