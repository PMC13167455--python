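"""Model-generated dyadic outcomes: directed overlap and encounter rates.

Directed proportional overlap (PO) is drawn from the hurdle-beta
social-relations model itself: correlated per-group focal/neighbour effects
(g_i, r_i), correlated within-dyad directed effects (d_ij, d_ji), and fixed
effects of focal size, neighbour size and their interaction on both the
hurdle (probability of zero overlap) and the beta-mean branch.  Symmetric
log encounter rates come from the multiple-membership model: both member
groups' effects load on every row with equal weight.

These generators define the ground truth for the dyadic inference stages;
geometric PO/encounter computation from utilization distributions lives in
:mod:`sympatry.dyadic`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from ..rng import substream
from ..truth import GenerativeTruth

__all__ = ["gen_srm_data", "gen_mm_data"]


def _bivariate(rng, n, sd1, sd2, rho):
    if not -1.0 < rho < 1.0:
        raise ValueError(
            f"implied 2x2 covariance is not positive definite (rho={rho})"
        )
    cov = np.array([[sd1**2, rho * sd1 * sd2], [rho * sd1 * sd2, sd2**2]])
    L = np.linalg.cholesky(cov)
    return rng.normal(size=(n, 2)) @ L.T


def _period_table(demography: pd.DataFrame, seasonal: bool) -> pd.DataFrame:
    if seasonal:
        df = demography.copy()
        df["period"] = df["year"].astype(str) + "-" + df["season"]
    else:
        df = demography[demography["season"] == "dry"].copy()
        df["season"] = "annual"
        df["period"] = df["year"].astype(str)
    return df


def gen_srm_data(
    truth: GenerativeTruth | None = None,
    demography: pd.DataFrame | None = None,
    seed: int = 0,
    seasonal: bool = True,
    return_effects: bool = False,
):
    """Directed dyad records drawn from the hurdle-beta SRM.

    Both directions of every dyad are emitted for every period in which both
    groups have a census size.  Varying effects are shared between the
    hurdle and the beta branch (the package's default branch-sharing
    structure).  With ``return_effects=True`` the sampled g/r/d effects are
    returned alongside for recovery oracles.
    """
    truth = truth or GenerativeTruth()
    truth.validate()
    if demography is None:
        raise ValueError("gen_srm_data requires a demography table")
    rng = substream(seed, "srm_data")
    s = truth.srm

    groups = sorted(demography["group_id"].unique())
    gr = _bivariate(rng, len(groups), s.sd_focal, s.sd_neighbour, s.rho_gr)
    g_eff = dict(zip(groups, gr[:, 0]))
    r_eff = dict(zip(groups, gr[:, 1]))

    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]
    dd = _bivariate(rng, len(pairs), s.sd_dyad, s.sd_dyad, s.rho_dd)
    d_eff = {}
    for (a, b), (dab, dba) in zip(pairs, dd):
        d_eff[(a, b)] = dab
        d_eff[(b, a)] = dba

    per = _period_table(demography, seasonal)
    sizes = per.set_index(["group_id", "period"])
    rows = []
    for period, sub in per.groupby("period"):
        present = sorted(sub["group_id"].unique())
        season = sub["season"].iloc[0]
        dry = 1.0 if season == "dry" else 0.0
        for f in present:
            for n in present:
                if f == n:
                    continue
                fz = float(sizes.loc[(f, period), "size_z"])
                nz = float(sizes.loc[(n, period), "size_z"])
                re = g_eff[f] + r_eff[n] + d_eff[(f, n)]
                eta_h = (
                    s.hurdle_intercept
                    + s.hurdle_focal * fz
                    + s.hurdle_neighbour * nz
                    + s.hurdle_fn * fz * nz
                    + s.hurdle_dry * dry
                    + re
                )
                eta_b = (
                    s.beta_intercept
                    + s.beta_focal * fz
                    + s.beta_neighbour * nz
                    + s.beta_fn * fz * nz
                    + s.beta_dry * dry
                    + s.beta_neighbour_dry * nz * dry
                    + re
                )
                theta = expit(eta_h)  # probability of zero overlap
                if rng.random() < theta:
                    po = 0.0
                else:
                    mu = expit(eta_b)
                    po = float(rng.beta(mu * s.phi, (1 - mu) * s.phi))
                    po = min(po, 1.0 - 1e-12)
                rows.append(
                    {
                        "focal_id": f,
                        "neighbour_id": n,
                        "dyad_id": f"{min(f, n)}~{max(f, n)}",
                        "period": period,
                        "season": season,
                        "focal_size": int(sizes.loc[(f, period), "size"]),
                        "neighbour_size": int(sizes.loc[(n, period), "size"]),
                        "focal_size_z": fz,
                        "neighbour_size_z": nz,
                        "po": po,
                    }
                )
    df = pd.DataFrame(rows)
    if return_effects:
        return df, {"g": g_eff, "r": r_eff, "d": d_eff}
    return df


def gen_mm_data(
    truth: GenerativeTruth | None = None,
    demography: pd.DataFrame | None = None,
    seed: int = 0,
    seasonal: bool = True,
    covariates: pd.DataFrame | None = None,
    return_effects: bool = False,
):
    """Symmetric pair-period encounter rates from the multiple-membership model.

    Covariates (absolute size difference, overlap-zone area and greenness)
    default to synthetic standardized values; a table indexed by
    ``dyad_id, period`` with columns ``overlap_area_z`` / ``overlap_ndvi_z``
    can be supplied to use geometric covariates instead.  The response is a
    positive encounter rate with a known per-row standard error of its log.
    """
    truth = truth or GenerativeTruth()
    truth.validate()
    if demography is None:
        raise ValueError("gen_mm_data requires a demography table")
    rng = substream(seed, "mm_data")
    m = truth.mm

    groups = sorted(demography["group_id"].unique())
    u_grp = dict(zip(groups, rng.normal(0.0, m.sd_group, len(groups))))
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]
    u_dyad = {
        f"{a}~{b}": rng.normal(0.0, m.sd_dyad) for a, b in pairs
    }

    cov_lookup = None
    if covariates is not None:
        cov_lookup = covariates.set_index(["dyad_id", "period"])

    per = _period_table(demography, seasonal)
    sizes = per.set_index(["group_id", "period"])
    rows = []
    for period, sub in per.groupby("period"):
        present = sorted(sub["group_id"].unique())
        season = sub["season"].iloc[0]
        dry = 1.0 if season == "dry" else 0.0
        for a, b in [(x, y) for i, x in enumerate(present) for y in present[i + 1 :]]:
            dyad = f"{a}~{b}"
            size_a = int(sizes.loc[(a, period), "size"])
            size_b = int(sizes.loc[(b, period), "size"])
            if cov_lookup is not None:
                if (dyad, period) not in cov_lookup.index:
                    continue
                area_z = float(cov_lookup.loc[(dyad, period), "overlap_area_z"])
                ndvi_z = float(cov_lookup.loc[(dyad, period), "overlap_ndvi_z"])
            else:
                area_z = rng.normal()
                ndvi_z = rng.normal()
            rows.append(
                {
                    "dyad_id": dyad,
                    "group_1": a,
                    "group_2": b,
                    "period": period,
                    "season": season,
                    "size_diff_abs": abs(size_a - size_b),
                    "overlap_area_z": area_z,
                    "overlap_ndvi_z": ndvi_z,
                    "_dry": dry,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no pair-periods available")
    sd = df["size_diff_abs"].std(ddof=1)
    df["size_diff_z"] = (
        0.0 if not sd > 0 else (df["size_diff_abs"] - df["size_diff_abs"].mean()) / sd
    )

    dry = df.pop("_dry").to_numpy()
    eta = (
        m.intercept
        + m.b_dry * dry
        + (m.b_sizediff + m.b_sizediff_dry * dry) * df["size_diff_z"].to_numpy()
        + (m.b_area + m.b_area_dry * dry) * df["overlap_area_z"].to_numpy()
        + (m.b_ndvi + m.b_ndvi_dry * dry) * df["overlap_ndvi_z"].to_numpy()
        + np.array([u_dyad[d] for d in df["dyad_id"]])
        + np.array([u_grp[a] for a in df["group_1"]])
        + np.array([u_grp[b] for b in df["group_2"]])
    )
    log_er_true = eta + rng.normal(0.0, m.sigma_resid, len(df))
    se = truth.noise.er_log_se * rng.uniform(0.8, 1.2, len(df))
    df["log_er"] = log_er_true + rng.normal(0.0, se)
    df["er"] = np.exp(df["log_er"])
    df["log_er_se"] = se
    if return_effects:
        return df, {"group": u_grp, "dyad": u_dyad}
    return df
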