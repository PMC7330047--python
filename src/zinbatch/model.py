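"""Density and likelihood computations of the hierarchical count model.

The observed-data likelihood of a cell mixes over cell types k:

    L = prod_{b,i} [ sum_k pi_bk prod_g Pr(Y_big | Theta) ]

with, per entry,

    Pr(Y=0)   = f_NB(0; mu, phi) + sum_{x>=1} logistic(g0 + g1 x) f_NB(x; mu, phi)
    Pr(Y=y>0) = (1 - logistic(g0 + g1 y)) f_NB(y; mu, phi)

where mu = exp(alpha_g + beta_gk + nu_bg + delta_bi). The infinite dropout
series is truncated at the smallest x whose NB upper-tail mass falls below
1e-14; since the logistic factor is bounded by one, the truncation error is
certified below that tail mass.

The `nzf` variant drops the zero inflation: Pr(Y=0) = f_NB(0) and
Pr(Y=y) = f_NB(y), sharing all other machinery.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import nbinom

from .data import ModelParameters, ObservedData
from . import _kernels

TAIL_MASS = 1e-14


def _check_counts(x) -> np.ndarray:
    x = np.asarray(x)
    if not np.all(np.isfinite(x)) or np.any(x < 0) or np.any(x != np.floor(x)):
        raise ValueError("x must be a non-negative integer")
    return x.astype(np.float64)


def nb_logpmf(x, mu, phi):
    """Log pmf of NB(mu, phi) with variance mu + mu^2/phi.

    Vectorized over all arguments; uses log-gamma so large x or phi do not
    overflow.
    """
    x = _check_counts(x)
    mu = np.asarray(mu, dtype=np.float64)
    phi = np.asarray(phi, dtype=np.float64)
    if np.any(mu <= 0) or np.any(phi <= 0):
        raise ValueError("mu and phi must be positive")
    out = (
        gammaln(phi + x)
        - gammaln(phi)
        - gammaln(x + 1.0)
        + x * np.log(mu / (mu + phi))
        + phi * np.log(phi / (mu + phi))
    )
    return out if out.ndim else float(out)


def dropout_prob(x, gamma0, gamma1):
    """Probability that a positive underlying count x is observed as zero.

    logistic(gamma0 + gamma1 * x), strictly decreasing in x (gamma1 < 0).
    """
    gamma1 = np.asarray(gamma1, dtype=np.float64)
    if np.any(gamma1 >= 0):
        raise ValueError("gamma1 must be negative (condition I)")
    eta = np.asarray(gamma0, dtype=np.float64) + gamma1 * np.asarray(x, dtype=np.float64)
    out = 1.0 / (1.0 + np.exp(-eta))
    return out if out.ndim else float(out)


def cell_mean(alpha_g, beta_gk, nu_bg, delta_bi):
    """NB mean exp(alpha_g + beta_gk + nu_bg + delta_bi)."""
    return np.exp(
        np.asarray(alpha_g, dtype=np.float64)
        + np.asarray(beta_gk, dtype=np.float64)
        + np.asarray(nu_bg, dtype=np.float64)
        + np.asarray(delta_bi, dtype=np.float64)
    )


def _truncation_point(mu: float, phi: float) -> int:
    """Smallest integer whose NB upper-tail mass is below TAIL_MASS."""
    q = nbinom.ppf(1.0 - TAIL_MASS, phi, phi / (phi + mu))
    return int(q) + 1 if np.isfinite(q) else 10_000_000


def zero_obs_logprob(mu: float, phi: float, gamma0: float, gamma1: float) -> float:
    """Log probability of observing a zero count (biological zero + dropout).

    log[ f_NB(0) + sum_{x>=1} logistic(gamma0 + gamma1 x) f_NB(x) ], with
    the series truncated at certified absolute error below the NB tail mass
    TAIL_MASS (the logistic factor is bounded by one).
    """
    if mu <= 0 or phi <= 0:
        raise ValueError("mu and phi must be positive")
    if gamma1 >= 0:
        raise ValueError("gamma1 must be negative (condition I)")
    xmax = _truncation_point(mu, phi)
    xs = np.arange(1, xmax + 1, dtype=np.float64)
    log_terms = (
        gammaln(phi + xs)
        - gammaln(phi)
        - gammaln(xs + 1.0)
        + xs * np.log(mu / (mu + phi))
        + phi * np.log(phi / (mu + phi))
        - np.logaddexp(0.0, -(gamma0 + gamma1 * xs))
    )
    log_f0 = phi * np.log(phi / (mu + phi))
    return float(logsumexp(np.concatenate(([log_f0], log_terms))))


def observed_loglik(
    data: ObservedData, params: ModelParameters, variant: str = "full"
) -> float:
    """Observed-data log-likelihood, mixing over cell types in log space.

    Parameters
    ----------
    variant
        "full" for the zero-inflated model, "nzf" for the reduced model
        without zero inflation.
    """
    if variant not in ("full", "nzf"):
        raise ValueError("variant must be 'full' or 'nzf'")
    params.validate()
    if params.G != data.G or params.B != data.B or params.delta.shape[0] != data.N:
        raise ValueError("dimension mismatch between data and params")
    return float(
        _kernels.observed_loglik_kernel(
            data.counts,
            data.batch0,
            params.alpha,
            params.beta,
            params.nu,
            params.delta,
            params.phi,
            params.gamma0,
            params.gamma1,
            params.pi,
            1 if variant == "nzf" else 0,
        )
    )
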