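"""Batch-effects-corrected counts by quantile matching with inverse sampling.

For each entry, the imputed underlying count x_hat sits at some quantile of
its fitted source distribution NB(exp(alpha + beta_w + nu_b + delta_i),
phi_bg). A uniform draw u from the CDF interval
(F_src(x_hat - 1), F_src(x_hat)] (with F(-1) := 0) is mapped through the
quantile function of the target distribution NB(exp(alpha + beta_w),
phi_1g) — the same cell type measured in the reference batch at unit size
factor. Because the distributions are discrete, several target integers may
share the interval; drawing u uniformly picks among them proportionally to
their target mass, avoiding the bias of always taking the minimum or
maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import nbinom

from .data import ObservedData


@dataclass
class CorrectedCounts:
    x_tilde: np.ndarray    # (G, N) non-negative integers
    u: np.ndarray          # (G, N) matching quantiles in (0, 1]
    seed: int


def _nb(mu, phi):
    return phi, phi / (phi + mu)


def correct_counts(fit, data: ObservedData, seed: int = 0) -> CorrectedCounts:
    """Quantile-match every entry to the reference batch's distribution.

    Requires fit.x_hat, fit.w_hat and the posterior means in
    fit.theta_hat. Deterministic given the seed.
    """
    for attr in ("x_hat", "w_hat", "theta_hat"):
        if getattr(fit, attr, None) is None:
            raise ValueError(f"fit is missing {attr}")
    p = fit.theta_hat
    if p.G != data.G or p.delta.shape[0] != data.N:
        raise ValueError("fit does not match the data's dimensions")
    rng = np.random.default_rng(seed)
    b0 = data.batch0
    w0 = np.asarray(fit.w_hat) - 1

    log_mu_bio = p.alpha[:, None] + p.beta[:, w0]
    mu_src = np.exp(log_mu_bio + p.nu[b0, :].T + p.delta[None, :])
    phi_src = p.phi[b0, :].T
    mu_tgt = np.exp(log_mu_bio)
    phi_tgt = np.broadcast_to(p.phi[0, :][:, None], mu_tgt.shape)

    x_hat = np.asarray(fit.x_hat)
    n_s, p_s = _nb(mu_src, phi_src)
    lo = np.where(x_hat > 0, nbinom.cdf(x_hat - 1, n_s, p_s), 0.0)
    hi = nbinom.cdf(x_hat, n_s, p_s)
    slo = nbinom.sf(x_hat, n_s, p_s)
    shi = np.where(x_hat > 0, nbinom.sf(x_hat - 1, n_s, p_s), 1.0)
    # u uniform on the half-open interval (lo, hi]; the same uniform draw
    # expressed in survival coordinates is v = 1 - u in [slo, shi)
    r = rng.random(x_hat.shape)
    u = hi - r * (hi - lo)
    v = slo + r * (shi - slo)

    n_t, p_t = _nb(mu_tgt, phi_tgt)
    # the CDF saturates at 1 in the upper tail, so match lower-tail entries
    # through the CDF quantile and upper-tail entries through the survival
    # function, where both coordinates keep full relative precision
    upper = hi > 0.5
    x_tilde = np.where(
        upper,
        nbinom.isf(np.maximum(v, 1e-300), n_t, p_t),
        nbinom.ppf(np.maximum(u, 1e-300), n_t, p_t),
    )
    x_tilde = np.maximum(np.nan_to_num(x_tilde, nan=0.0, posinf=0.0), 0.0)
    return CorrectedCounts(x_tilde=x_tilde.astype(np.int64), u=u, seed=seed)


def nb_quantile_interval(x, mu_src, phi_src, mu_tgt, phi_tgt):
    """The attainable corrected integers for a single entry: all q with
    F_tgt(q) in (F_src(x - 1), F_src(x)]. Mainly a didactic helper."""
    n_s, p_s = _nb(mu_src, phi_src)
    lo = nbinom.cdf(x - 1, n_s, p_s) if x > 0 else 0.0
    hi = nbinom.cdf(x, n_s, p_s)
    n_t, p_t = _nb(mu_tgt, phi_tgt)
    qlo = int(nbinom.ppf(min(lo + 1e-15, 1.0), n_t, p_t))
    if nbinom.cdf(qlo, n_t, p_t) <= lo:
        qlo += 1
    qhi = int(nbinom.ppf(hi, n_t, p_t))
    return lo, hi, list(range(qlo, qhi + 1))
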