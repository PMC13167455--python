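"""Posterior approximation engine.

Models are expressed as a differentiable negative log posterior over a
packed parameter vector.  Inference proceeds by (1) finding the joint
posterior mode with L-BFGS using analytic gradients, (2) building the
Hessian at the mode by central finite differences of the gradient, and
(3) drawing samples from the resulting Gaussian approximation.  Scale
parameters live on the log scale and correlations on the atanh scale, so
the Gaussian approximation is taken in an unconstrained space.

Priors are weakly regularizing throughout: Normal(0, 1) on standardized
coefficients, half-Normal(0, 1) on standard deviations, Normal(0, 1) on
log-scale auxiliary parameters (dispersion, shape, precision), and an
LKJ(2)-type prior on 2x2 correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize

__all__ = [
    "hpdi",
    "summarize",
    "PosteriorSummary",
    "PosteriorDraws",
    "ParamLayout",
    "laplace_fit",
    "normal_prior",
    "halfnormal_sd_prior",
    "lkj2_prior",
    "iid_block",
    "bivariate_block",
]


def hpdi(samples: np.ndarray, mass: float = 0.89) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the samples."""
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    s = np.sort(np.asarray(samples, dtype=float).ravel())
    n = len(s)
    if n == 0:
        raise ValueError("no samples")
    m = max(1, int(np.ceil(mass * n)))
    if m >= n:
        return float(s[0]), float(s[-1])
    widths = s[m - 1 :] - s[: n - m + 1]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + m - 1])


@dataclass
class PosteriorSummary:
    """Median, 89% HPDI and sign probability for one scalar estimand."""

    label: str
    median: float
    hpdi89: tuple[float, float]
    pp_gt0: float
    rhat: float = float("nan")
    ess: float = float("nan")

    def __post_init__(self) -> None:
        lo, hi = self.hpdi89
        if not lo <= self.median <= hi:
            raise ValueError("median must lie inside its HPDI")

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "median": self.median,
            "hpdi89_lo": self.hpdi89[0],
            "hpdi89_hi": self.hpdi89[1],
            "pp_gt0": self.pp_gt0,
            "rhat": self.rhat,
            "ess": self.ess,
        }


def _split_rhat_ess(x: np.ndarray, n_chains: int = 4) -> tuple[float, float]:
    """Split-R-hat and a crude ESS from a single sample vector."""
    n = (len(x) // n_chains) * n_chains
    if n < 2 * n_chains:
        return float("nan"), float("nan")
    chains = x[:n].reshape(n_chains, -1)
    m = chains.shape[1]
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b = m * means.var(ddof=1)
    if w <= 0:
        return 1.0, float(n)
    var_plus = (m - 1) / m * w + b / m
    rhat = float(np.sqrt(var_plus / w))
    # draws are iid by construction; report the raw count as ESS
    return rhat, float(n)


def summarize(samples: np.ndarray, label: str = "", mass: float = 0.89) -> PosteriorSummary:
    samples = np.asarray(samples, dtype=float).ravel()
    rhat, ess = _split_rhat_ess(samples)
    return PosteriorSummary(
        label=label,
        median=float(np.median(samples)),
        hpdi89=hpdi(samples, mass),
        pp_gt0=float(np.mean(samples > 0)),
        rhat=rhat,
        ess=ess,
    )


# ---------------------------------------------------------------------------
# parameter packing


class ParamLayout:
    """Named slices into a packed parameter vector."""

    def __init__(self) -> None:
        self._slices: dict[str, slice] = {}
        self._shapes: dict[str, tuple[int, ...]] = {}
        self.size = 0

    def add(self, name: str, shape: int | tuple[int, ...]) -> None:
        shape = (shape,) if isinstance(shape, int) else tuple(shape)
        n = int(np.prod(shape))
        self._slices[name] = slice(self.size, self.size + n)
        self._shapes[name] = shape
        self.size += n

    def get(self, theta: np.ndarray, name: str) -> np.ndarray:
        return theta[self._slices[name]].reshape(self._shapes[name])

    def slice(self, name: str) -> slice:
        return self._slices[name]

    def names(self) -> list[str]:
        return list(self._slices)


# ---------------------------------------------------------------------------
# prior / random-effect building blocks (negative log density + gradient)


def normal_prior(x: np.ndarray, grad: np.ndarray, sl: slice, sd: float = 1.0) -> float:
    v = x[sl]
    grad[sl] += v / sd**2
    return float(0.5 * np.sum(v**2) / sd**2)


def halfnormal_sd_prior(x: np.ndarray, grad: np.ndarray, sl: slice) -> float:
    """half-Normal(0,1) on sd, parameter stored as log sd (with Jacobian)."""
    ls = x[sl]
    sd2 = np.exp(2 * ls)
    grad[sl] += sd2 - 1.0
    return float(np.sum(0.5 * sd2 - ls))


def lkj2_prior(x: np.ndarray, grad: np.ndarray, sl: slice) -> float:
    """LKJ(2) on a 2x2 correlation, parameter stored as atanh(rho)."""
    c = x[sl]
    rho = np.clip(np.tanh(c), -0.999999, 0.999999)
    grad[sl] += 4.0 * rho
    return float(np.sum(-2.0 * np.log1p(-(rho**2))))


def iid_block(
    x: np.ndarray,
    grad: np.ndarray,
    u_sl: slice,
    ls_sl: slice,
) -> float:
    """u ~ Normal(0, sd^2) iid, sd = exp(log_sd)."""
    u = x[u_sl]
    sd = float(np.exp(x[ls_sl][0]))
    grad[u_sl] += u / sd**2
    grad[ls_sl] += -np.sum(u**2) / sd**2 + len(u)
    return float(0.5 * np.sum(u**2) / sd**2 + len(u) * np.log(sd))


def bivariate_block(
    x: np.ndarray,
    grad: np.ndarray,
    u_sl: slice,
    ls1_sl: slice,
    ls2_sl: slice,
    c_sl: slice,
) -> float:
    """Correlated pairs (u1, u2) ~ N(0, Sigma(sd1, sd2, rho)) per row.

    ``x[u_sl]`` holds pairs flattened row-major as (J, 2).
    """
    u = x[u_sl].reshape(-1, 2)
    J = len(u)
    s1, s2 = float(np.exp(x[ls1_sl][0])), float(np.exp(x[ls2_sl][0]))
    rho = float(np.clip(np.tanh(x[c_sl][0]), -0.999999, 0.999999))
    q = 1.0 / (1.0 - rho**2)
    a = u[:, 0] / s1
    b = u[:, 1] / s2
    quad = a**2 - 2 * rho * a * b + b**2
    nlp = float(
        0.5 * q * quad.sum()
        + J * (np.log(s1) + np.log(s2))
        + 0.5 * J * np.log(1.0 - rho**2)
    )
    gu = np.empty_like(u)
    gu[:, 0] = q * (a - rho * b) / s1
    gu[:, 1] = q * (b - rho * a) / s2
    grad[u_sl] += gu.ravel()
    grad[ls1_sl] += -q * np.sum(a * (a - rho * b)) + J
    grad[ls2_sl] += -q * np.sum(b * (b - rho * a)) + J
    grad[c_sl] += rho * q * quad.sum() - np.sum(a * b) - J * rho
    return nlp


# ---------------------------------------------------------------------------
# MAP + Laplace


@dataclass
class PosteriorDraws:
    """Posterior draws keyed by parameter name, plus fit diagnostics."""

    draws: dict[str, np.ndarray]
    theta_map: np.ndarray
    layout: ParamLayout
    converged: bool
    n_draws: int
    meta: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.draws[name]

    def max_rhat(self) -> float:
        vals = []
        for arr in self.draws.values():
            flat = arr.reshape(arr.shape[0], -1)
            for j in range(flat.shape[1]):
                vals.append(_split_rhat_ess(flat[:, j])[0])
        return float(np.nanmax(vals))

    def summary_table(self, names: list[str] | None = None) -> list[PosteriorSummary]:
        out = []
        for name in names or list(self.draws):
            arr = self.draws[name].reshape(self.n_draws, -1)
            for j in range(arr.shape[1]):
                label = name if arr.shape[1] == 1 else f"{name}[{j}]"
                out.append(summarize(arr[:, j], label))
        return out


def _fd_hessian(
    grad_fn: Callable[[np.ndarray], np.ndarray], x: np.ndarray
) -> np.ndarray:
    p = len(x)
    H = np.empty((p, p))
    for j in range(p):
        h = 1e-5 * (1.0 + abs(x[j]))
        e = np.zeros(p)
        e[j] = h
        H[:, j] = (grad_fn(x + e) - grad_fn(x - e)) / (2 * h)
    return 0.5 * (H + H.T)


def laplace_fit(
    nlp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    layout: ParamLayout,
    x0: np.ndarray,
    seed: int,
    n_draws: int = 2000,
    maxiter: int = 1000,
    meta: dict | None = None,
) -> PosteriorDraws:
    """Maximize the log posterior and draw from the Gaussian approximation."""
    # a generous box keeps line-search excursions out of overflow territory
    # (log-scale parameters beyond +-60 are absurd under the priors anyway);
    # stiff latent blocks can stall L-BFGS early, so restart from the
    # incumbent until the gradient is genuinely small
    x_start = x0
    res = None
    err_state = np.errstate(invalid="ignore", over="ignore", divide="ignore")
    err_state.__enter__()
    for _ in range(6):
        res = optimize.minimize(
            nlp_grad,
            x_start,
            jac=True,
            method="L-BFGS-B",
            bounds=[(-60.0, 60.0)] * len(x0),
            options={"maxiter": maxiter, "maxcor": 25, "ftol": 1e-14, "gtol": 1e-7},
        )
        if not np.all(np.isfinite(res.x)):
            raise RuntimeError(
                "posterior mode search diverged (non-finite parameters)"
            )
        grad_now = nlp_grad(res.x)[1]
        if np.max(np.abs(grad_now)) < 1e-2 or np.allclose(res.x, x_start):
            break
        x_start = res.x
    x_map = res.x

    grad_only = lambda x: nlp_grad(x)[1]
    H = _fd_hessian(grad_only, x_map)
    # ensure positive definiteness: small jitter first, eigenvalue
    # clipping (|ev|, floored) as the robust fallback for flat or slightly
    # indefinite directions left by an imperfect mode search
    jitter = 0.0
    eye = np.eye(len(x_map))
    L = None
    for _ in range(6):
        try:
            L = np.linalg.cholesky(H + jitter * eye)
            break
        except np.linalg.LinAlgError:
            jitter = max(1e-8, jitter * 100 if jitter else 1e-8)
    if L is None:
        ev, Q = np.linalg.eigh(H)
        floor = 1e-8 * max(1.0, float(np.abs(ev).max()))
        ev = np.maximum(np.abs(ev), floor)
        H = (Q * ev) @ Q.T
        L = np.linalg.cholesky(H + 1e-10 * eye)
        jitter = float("nan")

    err_state.__exit__(None, None, None)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((len(x_map), n_draws))
    # draws ~ N(x_map, H^{-1}): solve L^T x = z
    dev = np.linalg.solve(L.T, z)
    samples = x_map[None, :] + dev.T

    draws = {
        name: samples[:, layout.slice(name)].reshape(
            (n_draws,) + layout._shapes[name]
        )
        for name in layout.names()
    }
    return PosteriorDraws(
        draws=draws,
        theta_map=x_map,
        layout=layout,
        converged=bool(res.success),
        n_draws=n_draws,
        meta={**(meta or {}), "nlp": float(res.fun), "jitter": jitter},
    )
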