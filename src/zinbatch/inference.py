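"""Posterior summarization, diagnostics, model selection and DE detection.

Label switching across chains is resolved by optimal assignment on the
co-occurrence matrix of posterior-mode labels; convergence is assessed by
the estimated potential scale reduction (classic Gelman-Rubin R-hat) of the
log-scale type-specific expression theta_gk = alpha_g + beta_gk, the batch
effects nu_bg and the overdispersions phi_bg, with the rule that more than
80% of each group must fall below 1.3.

Intrinsic genes (differentially expressed between at least two cell types)
are called by thresholding the posterior null probabilities
xi_gk = Pr(L_gk = 0 | y) at the largest kappa0 <= 0.5 whose estimated
Bayesian FDR stays below the control level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .data import ModelParameters, ObservedData
from .mcmc import ChainSamples, HyperParameters, run_mcmc
from .model import observed_loglik


@dataclass
class FitSummary:
    """Posterior point summaries of a fitted model."""

    theta_hat: ModelParameters
    w_hat: np.ndarray                  # (N,) posterior-mode types, 1-based
    x_hat: np.ndarray                  # (G, N) imputed underlying counts
    xi: np.ndarray                     # (G, K-1) Pr(L_gk = 0 | y)
    w_prob: np.ndarray                 # (N, K) posterior type frequencies
    kappa0: float | None = None
    intrinsic_genes: np.ndarray | None = None
    bic: float | None = None
    loglik_hat: float | None = None

    @property
    def K(self) -> int:
        return self.theta_hat.K


@dataclass
class ConvergenceReport:
    epsr_theta: np.ndarray
    epsr_nu: np.ndarray
    epsr_phi: np.ndarray
    frac_below: dict
    converged: bool
    threshold: float = 1.3
    min_fraction: float = 0.8


@dataclass
class DropoutReport:
    """Per-batch observed zero rate, inferred dropout rate among zeros, and
    posterior-predictive mean zero rate."""

    rho0: np.ndarray
    rho_d: np.ndarray
    rho0_ppc: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "batch": np.arange(1, len(self.rho0) + 1),
            "zero_rate": self.rho0,
            "dropout_rate": self.rho_d,
            "ppc_zero_rate": self.rho0_ppc,
        })


def align_labels(reference, candidate) -> np.ndarray:
    """Permutation rho (1-based) mapping candidate labels onto the reference.

    rho[c - 1] = r means candidate label c is renamed to r; chosen to
    maximize agreement via optimal assignment on the co-occurrence matrix.
    Differing label counts are handled by padding the assignment problem
    with zero-agreement dummy labels.
    """
    reference = np.asarray(reference)
    candidate = np.asarray(candidate)
    if reference.shape != candidate.shape:
        raise ValueError("label vectors must have equal length")
    kr = int(reference.max())
    kc = int(candidate.max())
    k = max(kr, kc)
    co = np.zeros((k, k))
    for r, c in zip(reference, candidate):
        co[r - 1, c - 1] += 1
    rows, cols = linear_sum_assignment(-co)
    rho = np.empty(k, dtype=np.int64)
    rho[cols] = rows + 1
    return rho[:kc]


def apply_label_permutation(labels, rho) -> np.ndarray:
    """Rename labels (1-based) according to rho from align_labels."""
    return np.asarray(rho)[np.asarray(labels) - 1]


def _posterior_mode_w(samples: ChainSamples) -> np.ndarray:
    K = samples.K
    N = samples.W.shape[1]
    out = np.empty(N, dtype=np.int64)
    for i in range(N):
        out[i] = np.bincount(samples.W[:, i], minlength=K + 1)[1:].argmax() + 1
    return out


def _permute_chain(samples: ChainSamples, rho: np.ndarray) -> ChainSamples:
    """Relabel a chain's draws in place-safe copies according to rho.

    theta_gk = alpha + beta is permuted and re-anchored so that the new
    baseline column of beta is exactly zero; pi and W follow. L is
    permuted only when the baseline is fixed by rho (otherwise the
    spike-and-slab indicators have no exact counterpart)."""
    inv = np.argsort(rho - 1)        # inv[r-1] = old index of new label r
    theta = samples.alpha[:, :, None] + samples.beta     # (T, G, K)
    theta = theta[:, :, inv]
    alpha_new = theta[:, :, 0]
    beta_new = theta - alpha_new[:, :, None]
    W_new = np.asarray(rho)[samples.W - 1]
    pi_new = samples.pi[:, :, inv]
    L_new = samples.L
    if rho[0] == 1 and samples.L.shape[2] == len(rho) - 1:
        L_new = samples.L[:, :, inv[1:] - 1]
    out = ChainSamples(**{**samples.__dict__})
    out.alpha = alpha_new
    out.beta = beta_new
    out.W = W_new.astype(samples.W.dtype)
    out.pi = pi_new
    out.L = L_new
    return out


def align_chains(chains: list[ChainSamples]) -> tuple[list[ChainSamples], list]:
    """Align all chains' labels to the first chain; returns (chains, rhos)."""
    ref = _posterior_mode_w(chains[0])
    out = [chains[0]]
    rhos = [np.arange(1, chains[0].K + 1)]
    for ch in chains[1:]:
        rho = align_labels(ref, _posterior_mode_w(ch))
        out.append(_permute_chain(ch, rho))
        rhos.append(rho)
    return out, rhos


def summarize_posterior(samples) -> FitSummary:
    """Posterior means for continuous parameters, per-cell mode for W,
    rounded posterior-mean imputation for X, and xi_gk = Pr(L_gk = 0 | y).

    Accepts a single ChainSamples or a list (label-aligned first, pooled).
    """
    chains = samples if isinstance(samples, (list, tuple)) else [samples]
    if len(chains) == 0 or chains[0].T == 0:
        raise ValueError("no retained draws to summarize")
    baseline_ok = [True] * len(chains)
    if len(chains) > 1:
        chains, rhos = align_chains(list(chains))
        baseline_ok = [rho[0] == 1 for rho in rhos]

    data = chains[0].data
    K = chains[0].K

    def pooled(name):
        return np.concatenate([getattr(c, name) for c in chains], axis=0)

    alpha = pooled("alpha").mean(axis=0)
    beta = pooled("beta").mean(axis=0)
    nu = pooled("nu").mean(axis=0)
    delta = pooled("delta").mean(axis=0)
    phi = pooled("phi").mean(axis=0)
    gamma = pooled("gamma").mean(axis=0)
    pi = pooled("pi").mean(axis=0)
    # re-anchor the identifiability constraints (means of constrained entries
    # are exact zeros already; enforce against fp noise)
    beta[:, 0] = 0.0
    nu[0, :] = 0.0
    theta_hat = ModelParameters(
        alpha=alpha, beta=beta, nu=nu, delta=delta, phi=phi,
        gamma0=gamma[:, 0], gamma1=np.minimum(gamma[:, 1], -1e-10), pi=pi,
    )

    W_all = np.concatenate([c.W for c in chains], axis=0)
    N = W_all.shape[1]
    w_prob = np.empty((N, K))
    for i in range(N):
        w_prob[i] = np.bincount(W_all[:, i], minlength=K + 1)[1:] / W_all.shape[0]
    w_hat = w_prob.argmax(axis=1) + 1

    T_tot = sum(c.T for c in chains)
    sum_xd = sum(c.sum_x_dropout for c in chains)
    x_hat = data.counts.copy()
    zeros = data.counts == 0
    x_hat[zeros] = np.rint(sum_xd[zeros] / T_tot).astype(np.int64)

    xi_chains = [c for c, ok in zip(chains, baseline_ok) if ok]
    xi = np.concatenate(
        [1.0 - c.L.astype(np.float64) for c in xi_chains], axis=0
    ).mean(axis=0)

    return FitSummary(theta_hat=theta_hat, w_hat=w_hat, x_hat=x_hat,
                      xi=xi, w_prob=w_prob)


def _rhat(draws: np.ndarray) -> np.ndarray:
    """Classic potential scale reduction over axis (chain, iter, ...)."""
    m, n = draws.shape[0], draws.shape[1]
    means = draws.mean(axis=1)
    w = draws.var(axis=1, ddof=1).mean(axis=0)
    b_over_n = means.var(axis=0, ddof=1)
    vhat = (n - 1) / n * w + b_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt(vhat / w)
    r = np.where(w <= 0, 1.0, r)
    return r


def compute_epsr(chains: list[ChainSamples]) -> ConvergenceReport:
    """EPSR per scalar for theta_gk = alpha + beta, nu_bg (b >= 2), phi_bg.

    Requires >= 2 chains of equal retained length; labels are aligned
    across chains first. Convergence rule: > 80% of each group below 1.3.
    """
    if not isinstance(chains, (list, tuple)) or len(chains) < 2:
        raise ValueError("EPSR requires at least two chains")
    lengths = {c.T for c in chains}
    if len(lengths) != 1:
        raise ValueError("chains must have equal retained lengths")
    chains, _ = align_chains(list(chains))

    theta = np.stack([c.alpha[:, :, None] + c.beta for c in chains])
    nu = np.stack([c.nu[:, 1:, :] for c in chains])
    phi = np.stack([c.phi for c in chains])

    r_theta = _rhat(theta).ravel()
    r_nu = _rhat(nu).ravel()
    r_phi = _rhat(phi).ravel()
    frac = {
        "theta": float((r_theta < 1.3).mean()),
        "nu": float((r_nu < 1.3).mean()) if r_nu.size else 1.0,
        "phi": float((r_phi < 1.3).mean()),
    }
    return ConvergenceReport(
        epsr_theta=r_theta, epsr_nu=r_nu, epsr_phi=r_phi,
        frac_below=frac, converged=all(v > 0.8 for v in frac.values()),
    )


def parameter_count(B: int, G: int, K: int, n_b) -> int:
    """Effective number of free parameters used in the BIC penalty."""
    n_b = np.asarray(n_b)
    return int(K * (B + G) + 2 * B + (2 * B - 1) * G + (n_b - 1).sum())


def compute_bic(
    data: ObservedData, fit: FitSummary, K: int, variant: str = "full"
) -> float:
    """BIC(K) = -2 log L_o(theta_hat) + count * log(N * G)."""
    if fit.K != K:
        raise ValueError("fit does not correspond to the requested K")
    ll = observed_loglik(data, fit.theta_hat, variant=variant)
    pen = parameter_count(data.B, data.G, K, data.n_b)
    bic = -2.0 * ll + pen * np.log(float(data.N) * data.G)
    fit.loglik_hat = ll
    fit.bic = float(bic)
    return float(bic)


def select_K(
    data: ObservedData,
    K_range,
    hyper: HyperParameters | None = None,
    variant: str = "full",
    **mcmc_kwargs,
) -> tuple[int, pd.DataFrame]:
    """Fit every K in K_range and pick the BIC minimizer.

    Returns (K_hat, table); fits whose convergence could not be assessed
    (single chain) carry converged = None, failing ones are flagged, never
    dropped.
    """
    K_range = list(K_range)
    if not K_range:
        raise ValueError("K_range must be non-empty")
    rows = []
    fits = {}
    for K in K_range:
        chains = run_mcmc(data, K, hyper=hyper, variant=variant, **mcmc_kwargs)
        fit = summarize_posterior(chains if len(chains) > 1 else chains[0])
        bic = compute_bic(data, fit, K, variant=variant)
        conv = None
        if len(chains) >= 2:
            conv = compute_epsr(chains).converged
        rows.append({"K": K, "bic": bic, "loglik": fit.loglik_hat,
                     "converged": conv})
        fits[K] = fit
    table = pd.DataFrame(rows)
    k_hat = int(table.loc[table["bic"].idxmin(), "K"])
    table.attrs["fits"] = fits
    return k_hat, table


def detect_intrinsic_genes(xi: np.ndarray, alpha: float = 0.05):
    """Bayesian-FDR search for the intrinsic-gene set.

    Candidate thresholds are the observed xi values <= 0.5; kappa0 is the
    largest candidate whose estimated FDR(kappa) = sum xi * 1(xi<=kappa) /
    sum 1(xi<=kappa) is strictly below alpha. Genes with any called L_gk
    are intrinsic. Returns (gene indices, kappa0 or None).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    xi = np.asarray(xi, dtype=np.float64)
    flat = np.sort(xi.ravel())
    cand = np.unique(flat[flat <= 0.5])
    kappa0 = None
    for k in cand[::-1]:
        sel = flat <= k
        if flat[sel].sum() / sel.sum() < alpha:
            kappa0 = float(k)
            break
    if kappa0 is None:
        return np.array([], dtype=np.int64), None
    called = xi <= kappa0
    genes = np.flatnonzero(called.any(axis=1))
    return genes, kappa0


def dropout_report(data: ObservedData, fit: FitSummary, samples) -> DropoutReport:
    """Observed zero rates, inferred dropout rates among zeros, and the
    posterior-predictive mean zero rate per batch."""
    chains = samples if isinstance(samples, (list, tuple)) else [samples]
    B = data.B
    rho0 = np.empty(B)
    rho_d = np.full(B, np.nan)
    for b in range(B):
        cols = data.batch0 == b
        zeros = data.counts[:, cols] == 0
        rho0[b] = zeros.mean()
        nz = int(zeros.sum())
        if nz:
            rho_d[b] = int((fit.x_hat[:, cols][zeros] > 0).sum()) / nz
    ppc = np.concatenate([c.ppc_zero_rates for c in chains], axis=0)
    return DropoutReport(rho0=rho0, rho_d=rho_d, rho0_ppc=ppc.mean(axis=0))


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected agreement between two partitions (label-invariant,
    tolerates differing cluster counts)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(a, b))
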