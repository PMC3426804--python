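"""Beta-uniform mixture (BUM) model of p-values and model-based FDR.

The density on (0, 1] is

    f(x) = lambda + (1 - lambda) * alpha * x^(alpha - 1),

with 0 < alpha < 1 and 0 < lambda < 1: a uniform component of weight
lambda (the null genes) plus a Beta(alpha, 1) component whose peak near
zero carries the alternative.  The density at x = 1 is the logical upper
bound on the null proportion,

    pi_ub = lambda + (1 - lambda) * alpha,

so 1 - pi_ub lower-bounds the fraction of differentially expressed
genes.  The model-based FDR among genes called at p <= tau is

    FDR(tau) = pi_ub * tau / (lambda * tau + (1 - lambda) * tau^alpha),

which is nondecreasing in tau, enabling a bisection inverse for the
cutoff that achieves a target FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .exceptions import DegenerateInputError, InvalidInputError, InvalidParameterError

__all__ = [
    "BUMFit",
    "bum_density",
    "fit_bum",
    "pi_upper_bound",
    "bum_fdr_at_cutoff",
    "cutoff_for_target_fdr",
    "sample_bum",
]

_P_FLOOR = 1e-12
_LOGIT_BOUND = 30.0
# Deterministic multi-start grid in (alpha, lambda).
_STARTS = ((0.5, 0.5), (0.2, 0.8), (0.8, 0.2), (0.1, 0.5), (0.5, 0.9))


@dataclass(frozen=True)
class BUMFit:
    """Maximum-likelihood BUM fit and derived quantities."""

    alpha_hat: float
    lambda_hat: float
    loglik: float
    n: int
    converged: bool

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_hat < 1.0:
            raise InvalidParameterError(
                f"alpha_hat must lie in (0, 1), got {self.alpha_hat}"
            )
        if not 0.0 < self.lambda_hat < 1.0:
            raise InvalidParameterError(
                f"lambda_hat must lie in (0, 1), got {self.lambda_hat}"
            )

    @property
    def pi_ub(self) -> float:
        """Upper bound on the proportion of true-null (non-DE) genes."""
        return pi_upper_bound(self.alpha_hat, self.lambda_hat)

    def fdr_at(self, tau: float) -> float:
        return bum_fdr_at_cutoff(self, tau)

    def cutoff_for(self, target: float) -> float:
        return cutoff_for_target_fdr(self, target)


def _check_params(alpha: float, lam: float) -> None:
    # closed limits allowed for evaluation (alpha=1 or lambda=1 are the
    # flat/pure-null limits); the fitted model itself stays in the open box
    if not 0.0 < alpha <= 1.0:
        raise InvalidParameterError(f"alpha must lie in (0, 1], got {alpha}")
    if not 0.0 <= lam <= 1.0:
        raise InvalidParameterError(f"lambda must lie in [0, 1], got {lam}")


def bum_density(x, alpha: float, lam: float):
    """BUM density lambda + (1-lambda) alpha x^(alpha-1) on (0, 1]."""
    _check_params(alpha, lam)
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or np.any(x > 1):
        raise InvalidParameterError("x must lie in (0, 1]")
    out = lam + (1.0 - lam) * alpha * np.power(x, alpha - 1.0)
    return out if out.ndim else float(out)


def _nll(params: np.ndarray, logp: np.ndarray) -> float:
    alpha = special.expit(params[0])
    lam = special.expit(params[1])
    dens = lam + (1.0 - lam) * alpha * np.exp((alpha - 1.0) * logp)
    return -float(np.sum(np.log(dens)))


def fit_bum(p_values) -> BUMFit:
    """Fit the BUM model by maximum likelihood.

    Both parameters are logit-transformed to an unconstrained scale and
    optimised by L-BFGS-B from a fixed multi-start grid; p-values are
    floored at 1e-12 so numerically underflowed tests do not break the
    log-likelihood.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise InvalidInputError("cannot fit a BUM model to an empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InvalidInputError("p-values must be finite and lie in [0, 1]")
    if np.ptp(p) == 0:
        raise DegenerateInputError("all p-values identical; BUM fit is degenerate")
    if p.size < 100:
        warnings.warn(
            f"fitting BUM to only {p.size} p-values; estimates will be unstable",
            stacklevel=2,
        )
    logp = np.log(np.clip(p, _P_FLOOR, 1.0))

    best = None
    bounds = [(-_LOGIT_BOUND, _LOGIT_BOUND)] * 2
    for a0, l0 in _STARTS:
        x0 = np.array([special.logit(a0), special.logit(l0)])
        res = optimize.minimize(
            _nll,
            x0,
            args=(logp,),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    alpha = float(special.expit(best.x[0]))
    lam = float(special.expit(best.x[1]))
    eps = 1e-9
    alpha = min(max(alpha, eps), 1.0 - eps)
    lam = min(max(lam, eps), 1.0 - eps)
    return BUMFit(
        alpha_hat=alpha,
        lambda_hat=lam,
        loglik=-float(best.fun),
        n=int(p.size),
        converged=bool(best.success),
    )


def pi_upper_bound(alpha: float, lam: float) -> float:
    """Logical upper bound on the null proportion: lambda + (1-lambda) alpha."""
    _check_params(alpha, lam)
    return lam + (1.0 - lam) * alpha


def _fdr(alpha: float, lam: float, tau) -> np.ndarray:
    tau = np.asarray(tau, dtype=float)
    pi = lam + (1.0 - lam) * alpha
    denom = lam * tau + (1.0 - lam) * np.power(tau, alpha)
    return np.minimum(pi * tau / denom, 1.0)


def bum_fdr_at_cutoff(fit: BUMFit, tau) -> float:
    """Model-based FDR among genes with p <= tau, capped at 1."""
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr <= 0) or np.any(tau_arr > 1):
        raise InvalidParameterError("tau must lie in (0, 1]")
    out = _fdr(fit.alpha_hat, fit.lambda_hat, tau_arr)
    return out if out.ndim else float(out)


def cutoff_for_target_fdr(fit: BUMFit, target: float) -> float:
    """Largest p-value cutoff whose model-based FDR stays at or below target.

    FDR(tau) is nondecreasing, so the cutoff is found by bisection to an
    absolute tolerance of 1e-10.  Returns 1 when even FDR(1) = pi_ub
    meets the target, and 0 when no positive cutoff does.
    """
    if not 0.0 < target < 1.0:
        raise InvalidParameterError(f"target must lie in (0, 1), got {target}")
    alpha, lam = fit.alpha_hat, fit.lambda_hat
    if _fdr(alpha, lam, 1.0) <= target:
        return 1.0
    lo, hi = 0.0, 1.0  # FDR(lo+) <= target < FDR(hi)
    while hi - lo > 1e-10:
        mid = 0.5 * (lo + hi)
        if _fdr(alpha, lam, mid) <= target:
            lo = mid
        else:
            hi = mid
    return lo if lo > 1e-9 else 0.0


def sample_bum(n: int, alpha: float, lam: float, rng: np.random.Generator) -> np.ndarray:
    """Draw p-values from the BUM generative model.

    With probability lambda a draw is U(0, 1); otherwise it is
    Beta(alpha, 1), i.e. U^(1/alpha).
    """
    _check_params(alpha, lam)
    u = rng.random(n)
    is_null = rng.random(n) < lam
    return np.where(is_null, u, np.power(u, 1.0 / alpha))
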