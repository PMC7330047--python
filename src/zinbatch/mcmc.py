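"""Metropolis-within-Gibbs sampler with data augmentation.

One sweep updates, in order:

1. dropout indicators Z at observed zeros (Gibbs, underlying count
   collapsed), 2. underlying counts X at dropout entries (reflected integer
   random walk), 3. cell types W (categorical Gibbs) plus a joint
   (W_i, delta_i) mode-jumping Metropolis move, 4. compositions pi
   (conjugate Dirichlet), 5. dropout coefficients (gamma0, gamma1) (joint
   Metropolis, gamma1 < 0 enforced), 6. alpha, beta, nu, delta, phi
   (random-walk Metropolis; log-scale proposal for phi) plus per-batch
   group-offset moves along the alpha/nu-versus-delta ridges, 7. joint
   (L_gk, beta_gk) spike/slab flips, 8. slab probability p (conjugate
   Beta), 9. spike variance tau_beta0^2 (conjugate inverse-Gamma).

Constrained entries (beta[:, 0], nu[0, :], the first cell's delta per
batch) are never updated. Proposal scales adapt toward ~0.3 acceptance
during burn-in (Robbins-Monro) and are frozen afterwards.

The reduced `nzf` variant (negative binomial without zero inflation) fixes
Z = 0, X = Y and skips steps 1, 2 and 5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from . import _kernels
from .data import LatentState, ModelParameters, ObservedData


@dataclass
class HyperParameters:
    """Weakly informative prior settings (all overridable).

    The slab variance tau_beta1_sq is fixed large; the spike variance
    tau_beta0^2 gets an inverse-Gamma prior with small mean b_tau/(a_tau-1).
    """

    xi: float = 1.0                 # Dirichlet concentration for pi
    sigma_z0_sq: float = 100.0      # gamma_b0 prior variance
    a_gamma: float = 1.0            # Gamma prior on -gamma_b1 (shape)
    b_gamma: float = 1.0            # Gamma prior on -gamma_b1 (rate)
    m_a: float = 0.0
    sigma_a_sq: float = 100.0       # alpha prior
    m_c: float = 0.0
    sigma_c_sq: float = 100.0       # nu prior
    m_d: float = 0.0
    sigma_d_sq: float = 100.0       # delta prior
    kappa_phi: float = 1.0          # Gamma prior on phi (shape)
    tau_phi: float = 0.1            # Gamma prior on phi (rate)
    a_p: float = 1.0                # Beta prior on p
    b_p: float = 3.0
    a_tau: float = 2.0              # Inv-Gamma prior on tau_beta0^2
    b_tau: float = 0.01
    tau_beta1_sq: float = 100.0     # fixed slab variance

    def validate(self):
        for name in ("xi", "sigma_z0_sq", "a_gamma", "b_gamma", "sigma_a_sq",
                     "sigma_c_sq", "sigma_d_sq", "kappa_phi", "tau_phi",
                     "a_p", "b_p", "a_tau", "b_tau", "tau_beta1_sq"):
            if getattr(self, name) <= 0:
                raise ValueError(f"hyperparameter {name} must be positive")

    def to_dict(self):
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


class ChainState:
    """Mutable sampler state: parameters, latent variables, caches, scales."""

    def __init__(self, data: ObservedData, params: ModelParameters,
                 X: np.ndarray, Z: np.ndarray, W0: np.ndarray,
                 L: np.ndarray, p: float, tau0_sq: float):
        self.data = data
        self.batch0 = np.ascontiguousarray(data.batch0)
        self.anchor = np.zeros(data.N, dtype=np.int8)
        self.anchor_idx = np.ascontiguousarray(data.anchor_cells())
        self.anchor[self.anchor_idx] = 1
        order = np.argsort(self.batch0, kind="stable")
        self.bcells = np.ascontiguousarray(order)
        self.boff = np.concatenate(
            ([0], np.cumsum(np.bincount(self.batch0, minlength=data.B)))
        ).astype(np.int64)

        self.alpha = params.alpha.copy()
        self.beta = params.beta.copy()
        self.nu = params.nu.copy()
        self.delta = params.delta.copy()
        self.phi = params.phi.copy()
        self.gamma0 = params.gamma0.copy()
        self.gamma1 = params.gamma1.copy()
        self.pi = params.pi.copy()
        self.X = np.ascontiguousarray(X, dtype=np.int64)
        self.Z = np.ascontiguousarray(Z, dtype=np.int8)
        self.W0 = np.ascontiguousarray(W0, dtype=np.int64)   # 0-based labels
        self.L = np.ascontiguousarray(L, dtype=np.int8)      # (G, K), col 0 unused
        self.p = float(p)
        self.tau0_sq = float(tau0_sq)

        G, N = data.G, data.N
        B, K = data.B, self.beta.shape[1]
        self.s_alpha = np.full(G, 0.1)
        self.s_beta = np.full((G, K), 0.2)
        self.s_nu = np.full((B, G), 0.2)
        self.s_delta = np.full(N, 0.1)
        self.s_phi = np.full((B, G), 0.4)
        self.s_gamma = np.full((B, 2), 0.05)
        self.s_off = np.full(B, 0.05)
        self.s_toff = np.full(K, 0.05)
        self.s_x = np.array([2.0])
        self.iteration = 0
        self.refresh_caches()

    @property
    def K(self) -> int:
        return self.beta.shape[1]

    def refresh_caches(self):
        (self.ETA, self.LSE, self.LGA, self.LGX1, self.CUR,
         self.LGPHI, self.PHLP) = _kernels.init_caches(
            self.X, self.W0, self.batch0, self.alpha, self.beta,
            self.nu, self.delta, self.phi,
        )

    def params(self) -> ModelParameters:
        return ModelParameters(
            alpha=self.alpha.copy(), beta=self.beta.copy(), nu=self.nu.copy(),
            delta=self.delta.copy(), phi=self.phi.copy(),
            gamma0=self.gamma0.copy(), gamma1=self.gamma1.copy(),
            pi=self.pi.copy(),
        )

    def check_consistency(self):
        """Bug trap: (Y, X, Z) must satisfy the observation rule."""
        Y = self.data.counts
        if np.any((self.Z == 1) & ((Y != 0) | (self.X <= 0))):
            raise AssertionError("internal inconsistency: Z=1 needs Y=0, X>0")
        if np.any((self.Z == 0) & (self.X != Y)):
            raise AssertionError("internal inconsistency: Y != X at Z=0")


@dataclass
class ChainSamples:
    """Retained post-burn-in draws plus acceptance bookkeeping."""

    alpha: np.ndarray
    beta: np.ndarray
    nu: np.ndarray
    delta: np.ndarray
    phi: np.ndarray
    gamma: np.ndarray        # (T, B, 2)
    pi: np.ndarray
    W: np.ndarray            # (T, N) 1-based labels
    L: np.ndarray            # (T, G, K-1) indicators vs. type 1
    p: np.ndarray
    tau0_sq: np.ndarray
    sum_x_dropout: np.ndarray   # (G, N) sum of X over draws with Z=1
    cnt_dropout: np.ndarray     # (G, N) number of draws with Z=1
    ppc_zero_rates: np.ndarray  # (n_ppc, B) replicate zero rates per batch
    acceptance: dict
    n_iter: int
    burnin: int
    thin: int
    seed: int
    variant: str
    hyper: HyperParameters
    data: ObservedData

    @property
    def T(self) -> int:
        return self.alpha.shape[0]

    @property
    def K(self) -> int:
        return self.beta.shape[2]


def _size_factors(Y: np.ndarray) -> np.ndarray:
    """Median-of-ratios cell size factors, falling back to total counts."""
    ref = Y.mean(axis=1)
    pos = ref > 0
    sf = np.ones(Y.shape[1])
    if pos.sum() >= 30:
        R = Y[pos] / ref[pos, None]
        for i in range(Y.shape[1]):
            r = R[:, i]
            r = r[r > 0]
            sf[i] = np.median(r) if r.size >= 30 else np.nan
    bad = ~np.isfinite(sf) | (sf <= 0)
    if bad.any():
        tot = Y.sum(axis=0).astype(float)
        tot = np.maximum(tot, 1.0)
        sf[bad] = tot[bad] / np.median(tot)
    return sf


def initialize_chain(
    data: ObservedData,
    K: int,
    hyper: HyperParameters | None = None,
    seed: int = 0,
    variant: str = "full",
) -> ChainState:
    """Deterministic, data-driven starting point.

    Cell types come from k-means on scaled log counts; alpha from per-gene
    log means of the nonzero counts; beta and nu from empirical cluster and
    batch log-mean ratios; delta from log total-count ratios against the
    batch's first cell; phi by method of moments (floored); gamma at
    (0, -0.1); X equals Y except at zeros marked as provisional dropouts
    with probability one half, where a shifted NB draw fills in.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    hyper = hyper or HyperParameters()
    hyper.validate()
    rng = np.random.default_rng(seed)
    Y = data.counts
    G, N, B = data.G, data.N, data.B
    b0 = data.batch0

    sf = _size_factors(Y)
    Ys = Y / sf[None, :]
    logY = np.log1p(Ys)
    # location batch effects usually dwarf the type effects; center each
    # gene within each batch so k-means clusters by type, not by batch
    logY_c = logY.copy()
    for b in range(B):
        cols = b0 == b
        logY_c[:, cols] -= logY_c[:, cols].mean(axis=1, keepdims=True)

    labels = None
    for attempt in range(4):
        feats = logY_c.T if attempt == 0 else logY_c.T + rng.normal(
            0, 1e-3 * attempt, size=(N, G)
        )
        km = KMeans(n_clusters=K, n_init=10, random_state=int(seed % 2**31))
        cand = km.fit_predict(feats)
        if np.unique(cand).size == K:
            labels = cand.astype(np.int64)
            break
    if labels is None:
        raise ValueError(
            f"k-means could not resolve {K} distinct expression profiles"
        )

    alpha = np.empty(G)
    for g in range(G):
        nz = Y[g][Y[g] > 0]
        alpha[g] = np.log(nz.mean()) if nz.size else np.log(0.1)

    nu = np.zeros((B, G))
    ref_mean = Y[:, b0 == 0].mean(axis=1)
    for b in range(1, B):
        mb = Y[:, b0 == b].mean(axis=1)
        nu[b] = np.clip(np.log((mb + 0.5) / (ref_mean + 0.5)), -4, 4)

    # type effects from cluster means of batch-adjusted scaled counts
    beta = np.zeros((G, K))
    A = Ys / np.exp(nu[b0, :].T)
    m0 = A[:, labels == 0].mean(axis=1) if (labels == 0).any() else np.zeros(G)
    for k in range(1, K):
        sel = labels == k
        if sel.any():
            mk = A[:, sel].mean(axis=1)
            beta[:, k] = np.clip(np.log((mk + 0.5) / (m0 + 0.5)), -4, 4)

    tot = np.maximum(Y.sum(axis=0).astype(float), 1.0)
    anchors = data.anchor_cells()
    delta = np.log(tot / tot[anchors][b0])
    delta[anchors] = 0.0

    phi = np.empty((B, G))
    for b in range(B):
        Yb = Y[:, b0 == b].astype(float)
        m = Yb.mean(axis=1)
        v = Yb.var(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            est = m**2 / (v - m)
        est[~np.isfinite(est) | (est <= 0)] = 10.0
        phi[b] = np.clip(est, 0.1, 100.0)

    gamma0 = np.zeros(B)
    gamma1 = np.full(B, -0.1)

    pi = np.empty((B, K))
    for b in range(B):
        cnt = np.bincount(labels[b0 == b], minlength=K).astype(float)
        pi[b] = (cnt + hyper.xi) / (cnt.sum() + K * hyper.xi)

    X = Y.copy().astype(np.int64)
    Z = np.zeros((G, N), dtype=np.int8)
    if variant == "full":
        mu = np.minimum(
            np.exp(alpha[:, None] + beta[:, labels] + nu[b0].T + delta[None, :]),
            1e4,
        )
        drop = (Y == 0) & (rng.random((G, N)) < 0.5)
        phie = phi[b0].T
        X[drop] = 1 + rng.negative_binomial(
            phie[drop], phie[drop] / (phie[drop] + mu[drop])
        )
        Z[drop] = 1

    L = np.zeros((G, K), dtype=np.int8)
    L[:, 1:] = (np.abs(beta[:, 1:]) > 0.5).astype(np.int8)

    params = ModelParameters(
        alpha=alpha, beta=beta, nu=nu, delta=delta, phi=phi,
        gamma0=gamma0, gamma1=gamma1, pi=pi,
    )
    return ChainState(
        data, params, X, Z, labels, L,
        p=0.5, tau0_sq=hyper.b_tau / (hyper.a_tau - 1.0)
        if hyper.a_tau > 1 else 0.01,
    )


def state_from_truth(
    data: ObservedData, params: ModelParameters, latent: LatentState,
    hyper: HyperParameters | None = None,
) -> ChainState:
    """Chain state positioned exactly at a known parameter set (stationarity
    checks and fit-at-truth experiments)."""
    hyper = hyper or HyperParameters()
    K = params.K
    L = np.zeros((data.G, K), dtype=np.int8)
    L[:, 1:] = (params.beta[:, 1:] != 0).astype(np.int8)
    return ChainState(
        data, params, latent.X, latent.Z, np.asarray(latent.W) - 1, L,
        p=max(min(float(L[:, 1:].mean()), 0.95), 0.05),
        tau0_sq=hyper.b_tau / (hyper.a_tau - 1.0) if hyper.a_tau > 1 else 0.01,
    )


def gibbs_sweep(
    state: ChainState,
    hyper: HyperParameters,
    gain: float = 0.0,
    variant: str = "full",
    update_w: bool = True,
    joint_w_delta: bool = True,
) -> dict:
    """One full sweep over all blocks; returns per-block (accepts, proposals).

    update_w=False holds the cell-type labels fixed (used only while warm
    starting during burn-in); joint_w_delta gates the collapsed
    (W_i, delta_i) mode-jumping move (scheduled sparsely after burn-in,
    where it only needs to guard against rare late escapes)."""
    s = state
    k = _kernels
    Y = s.data.counts
    B = s.data.B
    acc = {}

    if variant == "full":
        k.update_dropouts(Y, s.X, s.Z, s.batch0, s.phi, s.gamma0, s.gamma1,
                          s.ETA, s.LSE, s.LGA, s.LGX1, s.CUR, s.LGPHI, s.PHLP)
        acc["x"] = k.update_x_rw(s.X, s.Z, s.batch0, s.phi, s.gamma0, s.gamma1,
                                 s.ETA, s.LSE, s.LGA, s.LGX1, s.CUR, s.s_x, gain)

    if update_w:
        k.update_w(s.X, s.batch0, s.alpha, s.beta, s.nu, s.delta, s.phi, s.pi,
                   s.W0, s.ETA, s.LSE, s.LGA, s.LGX1, s.CUR, s.LGPHI, s.PHLP)
        if joint_w_delta:
            acc["wdelta"] = k.update_w_delta_joint(
                Y, s.X, s.Z, s.batch0, s.alpha, s.beta, s.nu, s.delta, s.phi,
                s.gamma0, s.gamma1, s.pi, s.W0, s.anchor,
                s.ETA, s.LSE, s.LGA, s.LGX1, s.CUR, s.LGPHI, s.PHLP,
                s.s_delta, hyper.m_d, hyper.sigma_d_sq,
                1 if variant == "nzf" else 0)
    cells, off = k.build_type_index(s.W0, s.K)

    k.update_pi(s.W0, s.batch0, B, s.K, hyper.xi, s.pi)

    if variant == "full":
        a = k.update_gamma(s.X, s.Z, s.batch0, s.gamma0, s.gamma1,
                           hyper.sigma_z0_sq, hyper.a_gamma, hyper.b_gamma,
                           s.s_gamma, gain)
        acc["gamma"] = (a, B)

    acc["alpha"] = (
        k.update_alpha(s.X, s.alpha, s.phi, s.batch0, s.ETA, s.LSE, s.CUR,
                       s.s_alpha, hyper.m_a, hyper.sigma_a_sq, gain),
        s.data.G,
    )
    acc["beta"] = k.update_beta(s.X, s.beta, s.L, s.tau0_sq, hyper.tau_beta1_sq,
                                s.phi, s.batch0, cells, off,
                                s.ETA, s.LSE, s.CUR, s.s_beta, gain)
    acc["nu"] = k.update_nu(s.X, s.nu, s.phi, s.batch0, s.bcells, s.boff,
                            s.ETA, s.LSE, s.CUR, s.s_nu,
                            hyper.m_c, hyper.sigma_c_sq, gain)
    acc["delta"] = k.update_delta(s.X, s.delta, s.phi, s.batch0, s.anchor,
                                  s.ETA, s.LSE, s.CUR, s.s_delta,
                                  hyper.m_d, hyper.sigma_d_sq, gain)
    acc["phi"] = k.update_phi(s.X, s.phi, s.batch0, s.bcells, s.boff,
                              s.ETA, s.LSE, s.LGA, s.LGX1, s.CUR,
                              s.LGPHI, s.PHLP, s.s_phi,
                              hyper.kappa_phi, hyper.tau_phi, gain)
    acc["offset"] = (
        k.update_offsets(s.X, s.alpha, s.nu, s.delta, s.batch0, s.anchor_idx,
                         s.phi, s.ETA, s.LSE, s.CUR, s.LGA, s.LGX1,
                         s.LGPHI, s.PHLP, s.s_off,
                         hyper.m_a, hyper.sigma_a_sq, hyper.m_c,
                         hyper.sigma_c_sq, hyper.m_d, hyper.sigma_d_sq, gain),
        B,
    )
    acc["toffset"] = (
        k.update_type_offsets(s.X, s.beta, s.L, s.delta, s.batch0, s.anchor,
                              s.W0, s.phi, s.tau0_sq, hyper.tau_beta1_sq,
                              cells, off, s.ETA, s.LSE, s.LGA, s.LGX1, s.CUR,
                              s.LGPHI, s.PHLP, s.s_toff,
                              hyper.m_d, hyper.sigma_d_sq, gain),
        s.K - 1,
    )
    acc["lflip"] = k.update_lflip(s.X, s.beta, s.L, s.p, s.tau0_sq,
                                  hyper.tau_beta1_sq, s.phi, s.batch0,
                                  cells, off, s.ETA, s.LSE, s.CUR)
    s.p, s.tau0_sq = k.update_p_tau(s.beta, s.L, hyper.a_p, hyper.b_p,
                                    hyper.a_tau, hyper.b_tau)
    s.iteration += 1
    return acc


_STATE_ARRAYS = ("alpha", "beta", "nu", "delta", "phi", "gamma0", "gamma1",
                 "pi", "X", "Z", "W0", "L", "s_alpha", "s_beta", "s_nu",
                 "s_delta", "s_phi", "s_gamma", "s_off", "s_toff", "s_x")


def _snapshot(state: ChainState) -> dict:
    out = {n: getattr(state, n).copy() for n in _STATE_ARRAYS}
    out["p"] = state.p
    out["tau0_sq"] = state.tau0_sq
    return out


def _restore(state: ChainState, snap: dict):
    for n in _STATE_ARRAYS:
        getattr(state, n)[...] = snap[n]
    state.p = snap["p"]
    state.tau0_sq = snap["tau0_sq"]
    state.refresh_caches()


def _reseed_types(state: ChainState, labels: np.ndarray, hyper: HyperParameters):
    """Adopt a candidate labeling: set W, re-derive beta / L / pi empirically
    from batch- and size-adjusted underlying counts under the new labels."""
    K = state.K
    b0 = state.batch0
    state.W0[...] = labels
    A = state.X / np.exp(state.nu[b0, :].T + state.delta[None, :])
    m0 = A[:, labels == 0].mean(axis=1) if (labels == 0).any() else np.zeros(state.data.G)
    beta = np.zeros_like(state.beta)
    for k in range(1, K):
        sel = labels == k
        if sel.any():
            beta[:, k] = np.clip(
                np.log((A[:, sel].mean(axis=1) + 0.5) / (m0 + 0.5)), -4, 4
            )
    state.beta[...] = beta
    state.L[...] = 0
    state.L[:, 1:] = (np.abs(beta[:, 1:]) > 0.5).astype(np.int8)
    for b in range(state.data.B):
        cnt = np.bincount(labels[b0 == b], minlength=K).astype(float)
        state.pi[b] = (cnt + hyper.xi) / (cnt.sum() + K * hyper.xi)
    state.refresh_caches()


def _candidate_labelings(state: ChainState, seed: int):
    """Clusterings of model-corrected expression log1p(X / exp(nu + delta)),
    over a few feature sets for diversity."""
    K = state.K
    R = np.log1p(state.X / np.exp(state.nu[state.batch0, :].T
                                  + state.delta[None, :]))
    v = R.var(axis=1)
    G = R.shape[0]
    out = []
    feature_sets = [min(100, G), min(250, G), G]
    for r, ntop in enumerate(feature_sets):
        top = np.argsort(v)[::-1][:ntop]
        lab = KMeans(n_clusters=K, n_init=3,
                     random_state=(seed + 31 * r + 1) % 2**31).fit_predict(R[top].T)
        out.append(lab.astype(np.int64))
    bmag = np.abs(state.beta).max(axis=1)
    if bmag.max() > 0:
        top = np.argsort(bmag)[::-1][:min(150, G)]
        lab = KMeans(n_clusters=K, n_init=3,
                     random_state=(seed + 97) % 2**31).fit_predict(R[top].T)
        out.append(lab.astype(np.int64))
    return out


def warm_start(
    state: ChainState,
    hyper: HyperParameters,
    variant: str = "full",
    n_stages: int = 2,
    n_warm: int = 30,
    n_adapt: int = 25,
    seed: int = 0,
) -> ChainState:
    """Likelihood-guided label refinement before the main MCMC run.

    Mixture samplers with single-cell label updates are prone to
    initialization-dependent local modes: once the type profiles adapt to a
    wrong partition, per-cell Gibbs updates cannot repair it. This warm
    start alternates (a) short sweeps with the labels held fixed, letting
    the continuous parameters adapt, and (b) reclustering of the
    model-corrected expression matrix, where each candidate partition is
    aligned to the current one, given empirically re-derived type effects,
    adapted for a few sweeps, and scored by the observed-data
    log-likelihood; the best-scoring state is kept. Everything is seeded
    and deterministic; the subsequent MCMC run is untouched.
    """
    from .model import observed_loglik

    data = state.data
    if state.K < 2 or data.N < 10 * state.K:
        return state
    prev_best = -np.inf
    max_stages = n_stages + 1 if n_stages > 1 else n_stages
    stage = 0
    best_score = -np.inf
    while stage < n_stages:
        for t in range(n_warm):
            gibbs_sweep(state, hyper, gain=(t + 1.0) ** -0.6,
                        variant=variant, update_w=False)
        base = _snapshot(state)
        best = base
        best_score = observed_loglik(data, state.params(), variant=variant)
        for lab in _candidate_labelings(state, seed + 1000 * stage):
            from .inference import align_labels
            rho = align_labels(base["W0"] + 1, lab + 1)
            _restore(state, base)
            _reseed_types(state, rho[lab] - 1, hyper)
            for t in range(n_adapt):
                gibbs_sweep(state, hyper, gain=(t + 1.0) ** -0.6,
                            variant=variant, update_w=False)
            score = observed_loglik(data, state.params(), variant=variant)
            if score > best_score:
                best = _snapshot(state)
                best_score = score
        _restore(state, best)
        stage += 1
        # extend while the relabeling still improves the fit substantially
        if stage == n_stages and n_stages < max_stages \
                and best_score - prev_best > 0.002 * abs(best_score):
            n_stages += 1
        prev_best = best_score
    return state


def _ppc_zero_rates(samples_arrays, data, W_draws, idx, rng):
    """Zero rate per batch of replicate datasets simulated from stored draws."""
    alpha, beta, nu, delta, phi, gamma = samples_arrays
    b0 = data.batch0
    out = np.empty((len(idx), data.B))
    for j, t in enumerate(idx):
        w = W_draws[t] - 1
        mu = np.exp(alpha[t][:, None] + beta[t][:, w] + nu[t][b0].T
                    + delta[t][None, :])
        ph = phi[t][b0].T
        X = rng.negative_binomial(ph, ph / (ph + mu))
        eta = np.clip(gamma[t][b0, 0] + gamma[t][b0, 1] * X, -700, 700)
        pd = 1.0 / (1.0 + np.exp(-eta))
        Yrep = np.where((X > 0) & (rng.random(X.shape) < pd), 0, X)
        for b in range(data.B):
            out[j, b] = (Yrep[:, b0 == b] == 0).mean()
    return out


def run_mcmc(
    data: ObservedData,
    K: int,
    hyper: HyperParameters | None = None,
    n_iter: int = 4000,
    burnin: int = 2000,
    thin: int = 1,
    n_chains: int = 1,
    seed: int = 0,
    variant: str = "full",
    n_ppc: int = 100,
    check_every: int = 0,
    warm_start_stages: int = 2,
) -> list[ChainSamples]:
    """Run independent chains and return their retained draws.

    The default 4000 iterations with 2000 burn-in suit simulation-scale
    problems. Each chain is warm started (see warm_start; disable with
    warm_start_stages=0) before its n_iter sweeps. Chains receive distinct
    sub-seeds derived from `seed`; identical inputs reproduce identical
    ChainSamples bit for bit.
    """
    if not (0 <= burnin < n_iter):
        raise ValueError("need 0 <= burnin < n_iter")
    if thin < 1 or n_chains < 1:
        raise ValueError("thin and n_chains must be >= 1")
    if variant not in ("full", "nzf"):
        raise ValueError("variant must be 'full' or 'nzf'")
    hyper = hyper or HyperParameters()
    hyper.validate()

    child = np.random.SeedSequence(seed).generate_state(2 * n_chains)
    out = []
    for c in range(n_chains):
        init_seed = int(child[2 * c] & 0x7FFFFFFF)
        kern_seed = int(child[2 * c + 1] & 0x7FFFFFFF)
        state = initialize_chain(data, K, hyper, seed=init_seed, variant=variant)
        _kernels.seed_rng(kern_seed)
        if warm_start_stages > 0:
            warm_start(state, hyper, variant=variant,
                       n_stages=warm_start_stages, seed=init_seed)

        T = (n_iter - burnin + thin - 1) // thin
        G, N, B = data.G, data.N, data.B
        store = {
            "alpha": np.empty((T, G)),
            "beta": np.empty((T, G, K)),
            "nu": np.empty((T, B, G)),
            "delta": np.empty((T, N)),
            "phi": np.empty((T, B, G)),
            "gamma": np.empty((T, B, 2)),
            "pi": np.empty((T, B, K)),
            "W": np.empty((T, N), dtype=np.int32),
            "L": np.empty((T, G, max(K - 1, 0)), dtype=np.int8),
            "p": np.empty(T),
            "tau0_sq": np.empty(T),
        }
        sum_xd = np.zeros((G, N))
        cnt_d = np.zeros((G, N), dtype=np.int32)
        acc_tot: dict = {}
        t_out = 0
        for t in range(n_iter):
            gain = (t + 1.0) ** -0.6 if t < burnin else 0.0
            jwd = (t < burnin and t % 2 == 0) or (t >= burnin and (t - burnin) % 10 == 0)
            acc = gibbs_sweep(state, hyper, gain=gain, variant=variant,
                              joint_w_delta=jwd)
            if check_every and (t + 1) % check_every == 0:
                state.check_consistency()
            if t >= burnin:
                for key, v in acc.items():
                    a0, n0 = acc_tot.get(key, (0, 0))
                    acc_tot[key] = (a0 + v[0], n0 + v[1])
                if (t - burnin) % thin == 0:
                    store["alpha"][t_out] = state.alpha
                    store["beta"][t_out] = state.beta
                    store["nu"][t_out] = state.nu
                    store["delta"][t_out] = state.delta
                    store["phi"][t_out] = state.phi
                    store["gamma"][t_out, :, 0] = state.gamma0
                    store["gamma"][t_out, :, 1] = state.gamma1
                    store["pi"][t_out] = state.pi
                    store["W"][t_out] = state.W0 + 1
                    store["L"][t_out] = state.L[:, 1:]
                    store["p"][t_out] = state.p
                    store["tau0_sq"][t_out] = state.tau0_sq
                    mask = state.Z == 1
                    sum_xd[mask] += state.X[mask]
                    cnt_d += mask
                    t_out += 1

        rates = {key: (a / n if n else np.nan) for key, (a, n) in acc_tot.items()}
        rng = np.random.default_rng(kern_seed + 777)
        idx = np.unique(np.linspace(0, t_out - 1, min(n_ppc, t_out)).astype(int))
        ppc = _ppc_zero_rates(
            (store["alpha"], store["beta"], store["nu"], store["delta"],
             store["phi"], store["gamma"]),
            data, store["W"], idx, rng,
        )
        out.append(ChainSamples(
            alpha=store["alpha"], beta=store["beta"], nu=store["nu"],
            delta=store["delta"], phi=store["phi"], gamma=store["gamma"],
            pi=store["pi"], W=store["W"], L=store["L"], p=store["p"],
            tau0_sq=store["tau0_sq"],
            sum_x_dropout=sum_xd, cnt_dropout=cnt_d, ppc_zero_rates=ppc,
            acceptance=rates, n_iter=n_iter, burnin=burnin, thin=thin,
            seed=seed, variant=variant, hyper=hyper, data=data,
        ))
    return out


def dirichlet_posterior_params(W, batch_of_cell, B, K, xi) -> np.ndarray:
    """Parameters of the conjugate Dirichlet full conditional of pi,
    xi + per-batch type counts (labels 1-based)."""
    W = np.asarray(W)
    b0 = np.asarray(batch_of_cell) - 1
    out = np.full((B, K), float(xi))
    for b in range(B):
        out[b] += np.bincount(W[b0 == b] - 1, minlength=K)
    return out
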