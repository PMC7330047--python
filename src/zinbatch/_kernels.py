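"""Nopython kernels for the Metropolis-within-Gibbs sampler.

All heavy loops live here. The sampler state is held in plain numpy arrays
(0-based batch/type indices) and the blocks update it in place. Randomness
flows through numba's internal RNG, seeded once per chain with
``seed_rng``; given a seed and a fixed call order every sweep is
bit-reproducible.

To avoid recomputing the complete-data NB log-likelihood from scratch in
every Metropolis block, the following caches are maintained (all G x N):

    ETA  = alpha_g + beta_g,W(i) + nu_b,g + delta_i         (log mean)
    LSE  = log(exp(ETA) + phi_bg)
    LGA  = lgamma(X + phi_bg)
    LGX1 = lgamma(X + 1)
    CUR  = LGA - lgamma(phi) - LGX1 + X*ETA - (X+phi)*LSE + phi*log(phi)

so that CUR[g, i] is the NB log pmf of entry (g, i) at the current state,
plus the per-(batch, gene) scalars LGPHI = lgamma(phi), PHLP = phi*log(phi).
A mean-only move (alpha, beta, nu, delta) shifts ETA by d and changes the
entry log-likelihood by  x*d - (x+phi) * (log(exp(ETA+d)+phi) - LSE),
computed by ``delta_ll_eta``; phi and X moves recompute their lgamma terms.

Proposal scales adapt in log space toward a 0.3 acceptance rate during
burn-in (Robbins-Monro, gain passed by the caller; gain = 0 freezes).
"""

import math

import numpy as np
from numba import njit

TARGET_ACC = 0.3
TAIL = 1e-14
XCAP = 1_000_000  # hard cap on the dropout series (never reached for sane mu)


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def _softplus(e):
    if e > 30.0:
        return e
    return math.log1p(math.exp(e))


@njit(cache=True)
def nb_logpmf_scalar(x, mu, phi):
    return (
        math.lgamma(phi + x)
        - math.lgamma(phi)
        - math.lgamma(x + 1.0)
        + x * math.log(mu / (mu + phi))
        + phi * math.log(phi / (mu + phi))
    )


@njit(cache=True)
def zero_branch_masses(mu, phi, g0, g1):
    """(f0, S): NB mass at zero and the truncated dropout series
    S = sum_{x>=1} logistic(g0 + g1*x) * f_NB(x; mu, phi).

    Terms follow the pmf recurrence f(x+1) = f(x)*(phi+x)/(x+1)*mu/(mu+phi)
    with the logistic odds updated multiplicatively. The sum stops once
    either (a) the accumulated NB mass exceeds 1 - 1e-14, which certifies
    the truncation error because the logistic factor is bounded by one, or
    (b) the remaining dropout mass — at most logistic(g0 + g1*(x+1)) times
    the remaining NB mass, the logistic factor being decreasing — falls
    below 1e-12 of the accumulated total, which keeps the cost bounded for
    large-mean entries whose NB tail stretches far beyond the reach of the
    geometrically decaying logistic.
    """
    r = mu / (mu + phi)
    f = math.exp(phi * math.log(phi / (mu + phi)))
    f0 = f
    cum = f
    odds = math.exp(min(g0, 500.0))
    eg1 = math.exp(g1)
    s = 0.0
    x = 0
    while cum < 1.0 - TAIL and x < XCAP:
        f = f * (phi + x) / (x + 1.0) * r
        odds = odds * eg1
        s += odds / (1.0 + odds) * f
        cum += f
        x += 1
        bound = odds * eg1 * (1.0 - cum)
        if bound <= 1e-12 * (f0 + s) or bound <= 1e-300:
            break
    return f0, s


@njit(cache=True)
def sample_dropout_count(mu, phi, g0, g1, s, u):
    """Inverse-CDF draw from p(x) propto logistic(g0+g1*x)*f_NB(x), x >= 1.

    `s` must be the normalizer returned by zero_branch_masses; the draw
    never walks past the point where the remaining mass is negligible."""
    r = mu / (mu + phi)
    f = math.exp(phi * math.log(phi / (mu + phi)))
    odds = math.exp(min(g0, 500.0))
    eg1 = math.exp(g1)
    target = u * s
    acc = 0.0
    cum = f
    x = 0
    while x < XCAP:
        f = f * (phi + x) / (x + 1.0) * r
        odds = odds * eg1
        x += 1
        acc += odds / (1.0 + odds) * f
        cum += f
        if acc >= target:
            break
        if odds * eg1 * (1.0 - cum) <= 1e-300 or cum >= 1.0 - TAIL:
            break
    return x


@njit(cache=True)
def init_caches(X, W, batch, alpha, beta, nu, delta, phi):
    G, N = X.shape
    B = phi.shape[0]
    ETA = np.empty((G, N))
    LSE = np.empty((G, N))
    LGA = np.empty((G, N))
    LGX1 = np.empty((G, N))
    CUR = np.empty((G, N))
    LGPHI = np.empty((B, G))
    PHLP = np.empty((B, G))
    for b in range(B):
        for g in range(G):
            LGPHI[b, g] = math.lgamma(phi[b, g])
            PHLP[b, g] = phi[b, g] * math.log(phi[b, g])
    for g in range(G):
        for i in range(N):
            b = batch[i]
            ph = phi[b, g]
            e = alpha[g] + beta[g, W[i]] + nu[b, g] + delta[i]
            l = math.log(math.exp(e) + ph)
            x = X[g, i]
            ETA[g, i] = e
            LSE[g, i] = l
            LGA[g, i] = math.lgamma(x + ph)
            LGX1[g, i] = math.lgamma(x + 1.0)
            CUR[g, i] = (
                LGA[g, i] - LGPHI[b, g] - LGX1[g, i] + x * e - (x + ph) * l + PHLP[b, g]
            )
    return ETA, LSE, LGA, LGX1, CUR, LGPHI, PHLP


@njit(cache=True)
def delta_ll_eta(x, eta, lse, ph, d):
    """Change of one entry's NB log pmf when its log-mean shifts by d.

    Returns (delta loglik, new LSE value)."""
    lp = math.log(math.exp(eta + d) + ph)
    return x * d - (x + ph) * (lp - lse), lp


@njit(cache=True)
def delta_ll_phi_entry(x, eta, lga, lse, ph, php):
    """Change of one entry's NB log pmf (lgamma(phi), phi*log(phi) terms
    excluded — they are per-(batch, gene) constants handled by the caller)
    when the overdispersion moves ph -> php.

    Returns (delta, new lgamma(x+phi), new LSE)."""
    la = math.lgamma(x + php)
    lp = math.log(math.exp(eta) + php)
    return (la - lga) - (x + php) * lp + (x + ph) * lse, la, lp


@njit(cache=True)
def delta_ll_x_entry(x, xp, eta, lse, lga, lgx1, ph):
    """Change of one entry's NB log pmf when the underlying count moves
    x -> xp. Returns (delta, new lgamma(x+phi), new lgamma(x+1))."""
    lga_p = math.lgamma(xp + ph)
    lgx1_p = math.lgamma(xp + 1.0)
    d = (lga_p - lga) - (lgx1_p - lgx1) + (xp - x) * (eta - lse)
    return d, lga_p, lgx1_p


@njit(cache=True)
def update_dropouts(Y, X, Z, batch, phi, gamma0, gamma1,
                    ETA, LSE, LGA, LGX1, CUR, LGPHI, PHLP):
    """Step 1: exact (Z, X) Gibbs at Y = 0 entries.

    Z is drawn from its Bernoulli conditional with X collapsed (dropout
    mass S vs biological-zero mass f0); when Z = 1, X is drawn exactly by
    inverse CDF from p(x) propto logistic * NB on x >= 1.
    """
    G, N = Y.shape
    for g in range(G):
        for i in range(N):
            if Y[g, i] != 0:
                continue
            b = batch[i]
            ph = phi[b, g]
            mu = math.exp(ETA[g, i])
            f0, s = zero_branch_masses(mu, ph, gamma0[b], gamma1[b])
            tot = f0 + s
            znew = 0
            xnew = 0
            if tot > 0.0 and np.random.random() < s / tot:
                znew = 1
                xnew = sample_dropout_count(
                    mu, ph, gamma0[b], gamma1[b], s, np.random.random()
                )
            Z[g, i] = znew
            if xnew != X[g, i]:
                X[g, i] = xnew
                LGA[g, i] = math.lgamma(xnew + ph)
                LGX1[g, i] = math.lgamma(xnew + 1.0)
                CUR[g, i] = (
                    LGA[g, i] - LGPHI[b, g] - LGX1[g, i]
                    + xnew * ETA[g, i] - (xnew + ph) * LSE[g, i] + PHLP[b, g]
                )


@njit(cache=True)
def update_x_rw(X, Z, batch, phi, gamma0, gamma1,
                ETA, LSE, LGA, LGX1, CUR, s_x, gain):
    """Step 2: reflected integer random-walk Metropolis on X at Z = 1 entries.

    Proposals x' = x +/- m with m uniform on 1..ceil(s_x), reflected at the
    lower support bound (x' < 1 maps to 2 - x', a symmetric move).
    """
    G, N = X.shape
    acc = 0
    nprop = 0
    m_max = int(s_x[0]) + 1
    for g in range(G):
        for i in range(N):
            if Z[g, i] == 0:
                continue
            nprop += 1
            x = X[g, i]
            m = 1 + int(np.random.random() * m_max)
            if np.random.random() < 0.5:
                m = -m
            xp = x + m
            if xp < 1:
                xp = 2 - xp
            if xp == x:
                continue
            b = batch[i]
            ph = phi[b, g]
            lga_p = math.lgamma(xp + ph)
            lgx1_p = math.lgamma(xp + 1.0)
            dnb = (lga_p - LGA[g, i]) - (lgx1_p - LGX1[g, i]) \
                + (xp - x) * (ETA[g, i] - LSE[g, i])
            e0 = gamma0[b] + gamma1[b] * x
            e1 = gamma0[b] + gamma1[b] * xp
            dll = dnb + (e1 - _softplus(e1)) - (e0 - _softplus(e0))
            if math.log(np.random.random()) < dll:
                acc += 1
                X[g, i] = xp
                LGA[g, i] = lga_p
                LGX1[g, i] = lgx1_p
                CUR[g, i] += dnb
    if gain > 0.0 and nprop > 0:
        rate = acc / nprop
        s_x[0] *= math.exp(gain * (rate - TARGET_ACC))
        if s_x[0] < 1.0:
            s_x[0] = 1.0
        elif s_x[0] > 50.0:
            s_x[0] = 50.0
    return acc, nprop


@njit(cache=True)
def update_w(X, batch, alpha, beta, nu, delta, phi, pi, W,
             ETA, LSE, LGA, LGX1, CUR, LGPHI, PHLP):
    """Step 3: per-cell categorical draw of the cell type."""
    G, N = X.shape
    K = beta.shape[1]
    lp = np.empty(K)
    tk = np.empty((K, G))
    lsek = np.empty((K, G))
    for i in range(N):
        b = batch[i]
        for k in range(K):
            lp[k] = math.log(pi[b, k]) if pi[b, k] > 0.0 else -1e300
        for g in range(G):
            base = alpha[g] + nu[b, g] + delta[i]
            ph = phi[b, g]
            x = X[g, i]
            for k in range(K):
                if lp[k] <= -1e299:
                    continue
                e = base + beta[g, k]
                l = math.log(math.exp(e) + ph)
                tk[k, g] = e
                lsek[k, g] = l
                lp[k] += x * e - (x + ph) * l
        m = -1e308
        for k in range(K):
            if lp[k] > m:
                m = lp[k]
        tot = 0.0
        for k in range(K):
            lp[k] = math.exp(lp[k] - m)
            tot += lp[k]
        u = np.random.random() * tot
        knew = K - 1
        c = 0.0
        for k in range(K):
            c += lp[k]
            if u <= c:
                knew = k
                break
        if knew != W[i]:
            W[i] = knew
            for g in range(G):
                ph = phi[b, g]
                x = X[g, i]
                ETA[g, i] = tk[knew, g]
                LSE[g, i] = lsek[knew, g]
                CUR[g, i] = (
                    LGA[g, i] - LGPHI[b, g] - LGX1[g, i]
                    + x * tk[knew, g] - (x + ph) * lsek[knew, g] + PHLP[b, g]
                )


@njit(cache=True)
def update_w_delta_joint(Y, X, Z, batch, alpha, beta, nu, delta, phi,
                         gamma0, gamma1, pi, W, anchor,
                         ETA, LSE, LGA, LGX1, CUR, LGPHI, PHLP,
                         s_delta, m_d, v_d, nzf):
    """Step 3b: joint (W_i, delta_i) mode jump with (Z, X) collapsed.

    A cell stuck at a wrong type co-adapts both its size factor and its
    imputed dropout counts, so the single-site conditionals of W, delta and
    X all favor the status quo. This move proposes a uniformly drawn other
    type together with the compensating delta shift that preserves the
    cell's expected total count, delta' = delta + log(S_bk / S_bk') with
    S_bk = sum_g exp(alpha_g + beta_gk + nu_bg), plus symmetric Gaussian
    jitter (an involution with unit Jacobian). The acceptance ratio uses
    the cell's OBSERVED-data likelihood — the dropout indicators and
    underlying counts at observed zeros are integrated out — and on
    acceptance (Z, X) at the zero entries are redrawn from their exact
    conditionals under the new state, which together forms a valid
    partially collapsed Metropolis-within-Gibbs update.
    """
    G, N = Y.shape
    B, K = nu.shape[0], beta.shape[1]
    if K < 2:
        return 0, 0
    logS = np.empty((B, K))
    for b in range(B):
        for k in range(K):
            s = 0.0
            for g in range(G):
                s += math.exp(alpha[g] + beta[g, k] + nu[b, g])
            logS[b, k] = math.log(s)
    acc = 0
    nprop = 0
    for i in range(N):
        if anchor[i] == 1:
            continue
        nprop += 1
        b = batch[i]
        k = W[i]
        kp = int(np.random.random() * (K - 1))
        if kp >= k:
            kp += 1
        if pi[b, kp] <= 0.0:
            continue
        dp = delta[i] + (logS[b, k] - logS[b, kp]) \
            + s_delta[i] * np.random.normal()
        dll = math.log(pi[b, kp]) - math.log(pi[b, k])
        dll += ((delta[i] - m_d) ** 2 - (dp - m_d) ** 2) / (2.0 * v_d)
        for g in range(G):
            ph = phi[b, g]
            y = Y[g, i]
            e_cur = ETA[g, i]
            e_new = e_cur + (dp - delta[i]) + beta[g, kp] - beta[g, k]
            if y == 0 and nzf == 0:
                mu_c = math.exp(e_cur)
                mu_n = math.exp(e_new)
                f0c, sc = zero_branch_masses(mu_c, ph, gamma0[b], gamma1[b])
                f0n, sn = zero_branch_masses(mu_n, ph, gamma0[b], gamma1[b])
                if f0n + sn <= 0.0 or f0c + sc <= 0.0:
                    dll = -np.inf
                    break
                dll += math.log(f0n + sn) - math.log(f0c + sc)
            else:
                # observed count: NB ratio (the logistic factor at y does
                # not depend on W or delta); for nzf zeros y = x = 0
                lc = math.log(math.exp(e_cur) + ph)
                ln = math.log(math.exp(e_new) + ph)
                dll += y * (e_new - e_cur) - (y + ph) * (ln - lc)
        if math.log(np.random.random()) < dll:
            acc += 1
            W[i] = kp
            delta[i] = dp
            # recompute the cell's column under the new state
            for g in range(G):
                ph = phi[b, g]
                e = alpha[g] + beta[g, kp] + nu[b, g] + dp
                ETA[g, i] = e
                if Y[g, i] == 0 and nzf == 0:
                    mu = math.exp(e)
                    f0, s = zero_branch_masses(mu, ph, gamma0[b], gamma1[b])
                    tot = f0 + s
                    znew = 0
                    xnew = 0
                    if tot > 0.0 and np.random.random() < s / tot:
                        znew = 1
                        xnew = sample_dropout_count(
                            mu, ph, gamma0[b], gamma1[b], s, np.random.random()
                        )
                    Z[g, i] = znew
                    if xnew != X[g, i]:
                        X[g, i] = xnew
                        LGA[g, i] = math.lgamma(xnew + ph)
                        LGX1[g, i] = math.lgamma(xnew + 1.0)
                x = X[g, i]
                l = math.log(math.exp(e) + ph)
                LSE[g, i] = l
                CUR[g, i] = (LGA[g, i] - LGPHI[b, g] - LGX1[g, i]
                             + x * e - (x + ph) * l + PHLP[b, g])
    return acc, nprop


@njit(cache=True)
def update_pi(W, batch, B, K, xi, pi):
    """Step 4: conjugate Dirichlet(xi + counts) draw per batch."""
    counts = np.zeros((B, K))
    for i in range(W.shape[0]):
        counts[batch[i], W[i]] += 1.0
    for b in range(B):
        tot = 0.0
        for k in range(K):
            d = np.random.gamma(xi + counts[b, k], 1.0)
            pi[b, k] = d
            tot += d
        for k in range(K):
            pi[b, k] /= tot


@njit(cache=True)
def gamma_loglik(X, Z, batch, b, g0, g1):
    """Logistic-regression log-likelihood of the dropout indicators of batch b,
    over entries with a positive underlying count (the zero branch of the
    observed likelihood carries no logistic factor at x = 0)."""
    G, N = X.shape
    ll = 0.0
    for g in range(G):
        for i in range(N):
            if batch[i] != b:
                continue
            x = X[g, i]
            if x == 0:
                continue
            e = g0 + g1 * x
            ll += Z[g, i] * e - _softplus(e)
    return ll


@njit(cache=True)
def update_gamma(X, Z, batch, gamma0, gamma1, sigma_z0_sq, a_gamma, b_gamma,
                 s_gamma, gain):
    """Step 5: joint random-walk Metropolis on (gamma0, gamma1) per batch.

    Proposals with gamma1' >= 0 are rejected outright (condition I)."""
    B = gamma0.shape[0]
    acc = 0
    for b in range(B):
        g0 = gamma0[b]
        g1 = gamma1[b]
        g0p = g0 + s_gamma[b, 0] * np.random.normal()
        g1p = g1 + s_gamma[b, 1] * np.random.normal()
        a = 0
        if g1p < 0.0:
            dll = gamma_loglik(X, Z, batch, b, g0p, g1p) \
                - gamma_loglik(X, Z, batch, b, g0, g1)
            dll += (g0 * g0 - g0p * g0p) / (2.0 * sigma_z0_sq)
            dll += (a_gamma - 1.0) * (math.log(-g1p) - math.log(-g1)) \
                - b_gamma * (g1 - g1p)
            if math.log(np.random.random()) < dll:
                gamma0[b] = g0p
                gamma1[b] = g1p
                a = 1
                acc += 1
        if gain > 0.0:
            for j in range(2):
                s_gamma[b, j] *= math.exp(gain * (a - TARGET_ACC))
                if s_gamma[b, j] < 1e-4:
                    s_gamma[b, j] = 1e-4
                elif s_gamma[b, j] > 5.0:
                    s_gamma[b, j] = 5.0
    return acc


@njit(cache=True)
def update_alpha(X, alpha, phi, batch, ETA, LSE, CUR, s_alpha, m_a, v_a, gain):
    """Step 6a: random-walk Metropolis on alpha_g, vectorized over genes."""
    G, N = X.shape
    lse_p = np.empty(N)
    acc = 0
    for g in range(G):
        d = s_alpha[g] * np.random.normal()
        ap = alpha[g] + d
        dll = ((alpha[g] - m_a) ** 2 - (ap - m_a) ** 2) / (2.0 * v_a)
        for i in range(N):
            ph = phi[batch[i], g]
            dl, lp = delta_ll_eta(X[g, i], ETA[g, i], LSE[g, i], ph, d)
            lse_p[i] = lp
            dll += dl
        a = 0
        if math.log(np.random.random()) < dll:
            a = 1
            acc += 1
            alpha[g] = ap
            for i in range(N):
                ph = phi[batch[i], g]
                x = X[g, i]
                CUR[g, i] += x * d - (x + ph) * (lse_p[i] - LSE[g, i])
                LSE[g, i] = lse_p[i]
                ETA[g, i] += d
        if gain > 0.0:
            s_alpha[g] *= math.exp(gain * (a - TARGET_ACC))
            if s_alpha[g] < 1e-3:
                s_alpha[g] = 1e-3
            elif s_alpha[g] > 10.0:
                s_alpha[g] = 10.0
    return acc


@njit(cache=True)
def update_beta(X, beta, L, tau0_sq, tau1_sq, phi, batch, cells, off,
                ETA, LSE, CUR, s_beta, gain):
    """Step 6b: random-walk Metropolis on beta_gk (k >= 2), spike-and-slab
    prior N(0, tau_{L}^2); only cells currently of type k contribute."""
    G = X.shape[0]
    K = beta.shape[1]
    acc = 0
    nprop = 0
    lse_p = np.empty(X.shape[1])
    for k in range(1, K):
        c0 = off[k]
        c1 = off[k + 1]
        for g in range(G):
            nprop += 1
            d = s_beta[g, k] * np.random.normal()
            bp = beta[g, k] + d
            tau2 = tau1_sq if L[g, k] == 1 else tau0_sq
            dll = (beta[g, k] ** 2 - bp ** 2) / (2.0 * tau2)
            for ci in range(c0, c1):
                i = cells[ci]
                ph = phi[batch[i], g]
                dl, lp = delta_ll_eta(X[g, i], ETA[g, i], LSE[g, i], ph, d)
                lse_p[ci - c0] = lp
                dll += dl
            a = 0
            if math.log(np.random.random()) < dll:
                a = 1
                acc += 1
                beta[g, k] = bp
                for ci in range(c0, c1):
                    i = cells[ci]
                    ph = phi[batch[i], g]
                    x = X[g, i]
                    CUR[g, i] += x * d - (x + ph) * (lse_p[ci - c0] - LSE[g, i])
                    LSE[g, i] = lse_p[ci - c0]
                    ETA[g, i] += d
            if gain > 0.0:
                s_beta[g, k] *= math.exp(gain * (a - TARGET_ACC))
                if s_beta[g, k] < 1e-3:
                    s_beta[g, k] = 1e-3
                elif s_beta[g, k] > 10.0:
                    s_beta[g, k] = 10.0
    return acc, nprop


@njit(cache=True)
def update_nu(X, nu, phi, batch, bcells, boff, ETA, LSE, CUR, s_nu, m_c, v_c, gain):
    """Step 6c: random-walk Metropolis on nu_bg for b >= 2."""
    G = X.shape[0]
    B = nu.shape[0]
    acc = 0
    nprop = 0
    lse_p = np.empty(X.shape[1])
    for b in range(1, B):
        c0 = boff[b]
        c1 = boff[b + 1]
        for g in range(G):
            nprop += 1
            d = s_nu[b, g] * np.random.normal()
            np_ = nu[b, g] + d
            ph = phi[b, g]
            dll = ((nu[b, g] - m_c) ** 2 - (np_ - m_c) ** 2) / (2.0 * v_c)
            for ci in range(c0, c1):
                i = bcells[ci]
                dl, lp = delta_ll_eta(X[g, i], ETA[g, i], LSE[g, i], ph, d)
                lse_p[ci - c0] = lp
                dll += dl
            a = 0
            if math.log(np.random.random()) < dll:
                a = 1
                acc += 1
                nu[b, g] = np_
                for ci in range(c0, c1):
                    i = bcells[ci]
                    x = X[g, i]
                    CUR[g, i] += x * d - (x + ph) * (lse_p[ci - c0] - LSE[g, i])
                    LSE[g, i] = lse_p[ci - c0]
                    ETA[g, i] += d
            if gain > 0.0:
                s_nu[b, g] *= math.exp(gain * (a - TARGET_ACC))
                if s_nu[b, g] < 1e-3:
                    s_nu[b, g] = 1e-3
                elif s_nu[b, g] > 10.0:
                    s_nu[b, g] = 10.0
    return acc, nprop


@njit(cache=True)
def update_delta(X, delta, phi, batch, anchor, ETA, LSE, CUR, s_delta, m_d, v_d, gain):
    """Step 6d: random-walk Metropolis on delta_i (skipping anchor cells)."""
    G, N = X.shape
    acc = 0
    nprop = 0
    lse_p = np.empty(G)
    for i in range(N):
        if anchor[i] == 1:
            continue
        nprop += 1
        b = batch[i]
        d = s_delta[i] * np.random.normal()
        dp = delta[i] + d
        dll = ((delta[i] - m_d) ** 2 - (dp - m_d) ** 2) / (2.0 * v_d)
        for g in range(G):
            ph = phi[b, g]
            dl, lp = delta_ll_eta(X[g, i], ETA[g, i], LSE[g, i], ph, d)
            lse_p[g] = lp
            dll += dl
        a = 0
        if math.log(np.random.random()) < dll:
            a = 1
            acc += 1
            delta[i] = dp
            for g in range(G):
                ph = phi[b, g]
                x = X[g, i]
                CUR[g, i] += x * d - (x + ph) * (lse_p[g] - LSE[g, i])
                LSE[g, i] = lse_p[g]
                ETA[g, i] += d
        if gain > 0.0:
            s_delta[i] *= math.exp(gain * (a - TARGET_ACC))
            if s_delta[i] < 1e-3:
                s_delta[i] = 1e-3
            elif s_delta[i] > 10.0:
                s_delta[i] = 10.0
    return acc, nprop


@njit(cache=True)
def update_phi(X, phi, batch, bcells, boff, ETA, LSE, LGA, LGX1, CUR,
               LGPHI, PHLP, s_phi, kappa_phi, tau_phi, gain):
    """Step 6e: log-scale random-walk Metropolis on phi_bg (Gamma prior)."""
    G = X.shape[0]
    B = phi.shape[0]
    acc = 0
    nprop = 0
    nmax = 0
    for b in range(B):
        if boff[b + 1] - boff[b] > nmax:
            nmax = boff[b + 1] - boff[b]
    lga_p = np.empty(nmax)
    lse_p = np.empty(nmax)
    for b in range(B):
        c0 = boff[b]
        c1 = boff[b + 1]
        nb = c1 - c0
        for g in range(G):
            nprop += 1
            ph = phi[b, g]
            php = ph * math.exp(s_phi[b, g] * np.random.normal())
            lgphi_p = math.lgamma(php)
            phlp_p = php * math.log(php)
            # prior + Jacobian of the log-scale proposal
            dll = kappa_phi * (math.log(php) - math.log(ph)) - tau_phi * (php - ph)
            dll += nb * (phlp_p - PHLP[b, g]) - nb * (lgphi_p - LGPHI[b, g])
            for ci in range(c0, c1):
                i = bcells[ci]
                x = X[g, i]
                la = math.lgamma(x + php)
                lp = math.log(math.exp(ETA[g, i]) + php)
                lga_p[ci - c0] = la
                lse_p[ci - c0] = lp
                dll += (la - LGA[g, i]) - (x + php) * lp + (x + ph) * LSE[g, i]
            a = 0
            if math.log(np.random.random()) < dll:
                a = 1
                acc += 1
                phi[b, g] = php
                LGPHI[b, g] = lgphi_p
                PHLP[b, g] = phlp_p
                for ci in range(c0, c1):
                    i = bcells[ci]
                    x = X[g, i]
                    LGA[g, i] = lga_p[ci - c0]
                    LSE[g, i] = lse_p[ci - c0]
                    CUR[g, i] = (
                        LGA[g, i] - lgphi_p - LGX1[g, i]
                        + x * ETA[g, i] - (x + php) * LSE[g, i] + phlp_p
                    )
            if gain > 0.0:
                s_phi[b, g] *= math.exp(gain * (a - TARGET_ACC))
                if s_phi[b, g] < 1e-3:
                    s_phi[b, g] = 1e-3
                elif s_phi[b, g] > 5.0:
                    s_phi[b, g] = 5.0
    return acc, nprop


@njit(cache=True)
def update_offsets(X, alpha, nu, delta, batch, anchor_cells, phi,
                   ETA, LSE, CUR, LGA, LGX1, LGPHI, PHLP,
                   s_off, m_a, v_a, m_c, v_c, m_d, v_d, gain):
    """Step 6f: joint ridge moves for the location offsets.

    The likelihood is invariant under "alpha_g + c for all g, delta_i - c
    for all cells" except at the per-batch anchor cells whose delta is
    pinned at zero (and likewise for "nu_bg + c, delta_i - c" within one
    batch). Single-site random walks diffuse along these ridges extremely
    slowly, so the posterior mean of delta can retain a batch-wide offset
    for thousands of sweeps. These Metropolis moves propose a coordinated
    shift; only the anchor columns' likelihood changes, so a move costs
    O(G * B).

    Move 0: alpha += c, delta -= c at all non-anchor cells.
    Move b >= 1: nu[b] += c, delta -= c at batch b's non-anchor cells.
    """
    G, N = X.shape
    B = nu.shape[0]
    acc = 0
    lse_p = np.empty((B, G))
    for b in range(B):
        c = s_off[b] * np.random.normal()
        if b == 0:
            # priors: alpha shifts everywhere, delta shifts at non-anchors
            dll = 0.0
            for g in range(G):
                dll += ((alpha[g] - m_a) ** 2 - (alpha[g] + c - m_a) ** 2) \
                    / (2.0 * v_a)
            for i in range(N):
                skip = False
                for bb in range(B):
                    if anchor_cells[bb] == i:
                        skip = True
                if skip:
                    continue
                dll += ((delta[i] - m_d) ** 2 - (delta[i] - c - m_d) ** 2) \
                    / (2.0 * v_d)
            # likelihood changes only at the anchor columns
            for bb in range(B):
                i = anchor_cells[bb]
                for g in range(G):
                    ph = phi[bb, g]
                    dl, lp = delta_ll_eta(X[g, i], ETA[g, i], LSE[g, i], ph, c)
                    lse_p[bb, g] = lp
                    dll += dl
            if math.log(np.random.random()) < dll:
                acc += 1
                for g in range(G):
                    alpha[g] += c
                for i in range(N):
                    skip = False
                    for bb in range(B):
                        if anchor_cells[bb] == i:
                            skip = True
                    if not skip:
                        delta[i] -= c
                for bb in range(B):
                    i = anchor_cells[bb]
                    for g in range(G):
                        ph = phi[bb, g]
                        x = X[g, i]
                        CUR[g, i] += x * c - (x + ph) * (lse_p[bb, g] - LSE[g, i])
                        LSE[g, i] = lse_p[bb, g]
                        ETA[g, i] += c
                a = 1
            else:
                a = 0
        else:
            dll = 0.0
            for g in range(G):
                dll += ((nu[b, g] - m_c) ** 2 - (nu[b, g] + c - m_c) ** 2) \
                    / (2.0 * v_c)
            ia = anchor_cells[b]
            for i in range(N):
                if batch[i] != b or i == ia:
                    continue
                dll += ((delta[i] - m_d) ** 2 - (delta[i] - c - m_d) ** 2) \
                    / (2.0 * v_d)
            for g in range(G):
                ph = phi[b, g]
                dl, lp = delta_ll_eta(X[g, ia], ETA[g, ia], LSE[g, ia], ph, c)
                lse_p[b, g] = lp
                dll += dl
            if math.log(np.random.random()) < dll:
                acc += 1
                for g in range(G):
                    nu[b, g] += c
                for i in range(N):
                    if batch[i] == b and i != ia:
                        delta[i] -= c
                for g in range(G):
                    ph = phi[b, g]
                    x = X[g, ia]
                    CUR[g, ia] += x * c - (x + ph) * (lse_p[b, g] - LSE[g, ia])
                    LSE[g, ia] = lse_p[b, g]
                    ETA[g, ia] += c
                a = 1
            else:
                a = 0
        if gain > 0.0:
            s_off[b] *= math.exp(gain * (a - TARGET_ACC))
            if s_off[b] < 1e-3:
                s_off[b] = 1e-3
            elif s_off[b] > 2.0:
                s_off[b] = 2.0
    return acc


@njit(cache=True)
def update_type_offsets(X, beta, L, delta, batch, anchor, W, phi,
                        tau0_sq, tau1_sq, cells, off,
                        ETA, LSE, LGA, LGX1, CUR, LGPHI, PHLP,
                        s_toff, m_d, v_d, gain):
    """Step 6g: per-type group moves along the beta-versus-delta ridge.

    Shifting a whole type-effect column, beta_gk + c for all g, while
    moving delta_i - c for the cells currently of type k leaves their
    likelihood unchanged; the restoring force lives in the spike-and-slab
    prior of beta (a coherent shift pushes the null genes off zero, which
    the sampled spike variance would otherwise slowly inflate to absorb),
    the delta priors, and any anchor cell of type k whose delta is pinned.
    A coordinated Metropolis move makes that gradient actable in one step;
    single-site updates cannot traverse the ridge.
    """
    G, N = X.shape
    K = beta.shape[1]
    acc = 0
    lse_p = np.empty(G)
    for k in range(1, K):
        c = s_toff[k] * np.random.normal()
        dll = 0.0
        for g in range(G):
            tau2 = tau1_sq if L[g, k] == 1 else tau0_sq
            dll += (beta[g, k] ** 2 - (beta[g, k] + c) ** 2) / (2.0 * tau2)
        # delta prior terms and the anchor cells of this type
        n_anchor = 0
        anchor_i = -1
        for ci in range(off[k], off[k + 1]):
            i = cells[ci]
            if anchor[i] == 1:
                n_anchor += 1
                anchor_i = i
                b = batch[i]
                for g in range(G):
                    ph = phi[b, g]
                    dl, lp = delta_ll_eta(X[g, i], ETA[g, i], LSE[g, i], ph, c)
                    lse_p[g] = lp
                    dll += dl
            else:
                dll += ((delta[i] - m_d) ** 2 - (delta[i] - c - m_d) ** 2) \
                    / (2.0 * v_d)
        if n_anchor > 1:
            # more than one pinned cell: skip rather than track several
            # changed columns (rare; only multi-anchor types)
            continue
        a = 0
        if math.log(np.random.random()) < dll:
            a = 1
            acc += 1
            for g in range(G):
                beta[g, k] += c
            for ci in range(off[k], off[k + 1]):
                i = cells[ci]
                if anchor[i] == 1:
                    b = batch[i]
                    for g in range(G):
                        ph = phi[b, g]
                        x = X[g, i]
                        CUR[g, i] += x * c - (x + ph) * (lse_p[g] - LSE[g, i])
                        LSE[g, i] = lse_p[g]
                        ETA[g, i] += c
                else:
                    delta[i] -= c
        if gain > 0.0:
            s_toff[k] *= math.exp(gain * (a - TARGET_ACC))
            if s_toff[k] < 1e-3:
                s_toff[k] = 1e-3
            elif s_toff[k] > 2.0:
                s_toff[k] = 2.0
    return acc


@njit(cache=True)
def update_lflip(X, beta, L, p, tau0_sq, tau1_sq, phi, batch, cells, off,
                 ETA, LSE, CUR):
    """Step 7: joint (L_gk, beta_gk) flip.

    Proposes L' = 1 - L with a fresh beta' drawn from the proposed
    component's prior; the prior and proposal densities of beta cancel, so
    the acceptance ratio is the likelihood ratio times (p/(1-p))^(L'-L).
    """
    G = X.shape[0]
    K = beta.shape[1]
    acc = 0
    nprop = 0
    lse_p = np.empty(X.shape[1])
    lpodds = math.log(p) - math.log1p(-p)
    for k in range(1, K):
        c0 = off[k]
        c1 = off[k + 1]
        for g in range(G):
            nprop += 1
            lnew = 1 - L[g, k]
            tau2 = tau1_sq if lnew == 1 else tau0_sq
            bp = math.sqrt(tau2) * np.random.normal()
            d = bp - beta[g, k]
            dll = lpodds * (lnew - L[g, k])
            for ci in range(c0, c1):
                i = cells[ci]
                ph = phi[batch[i], g]
                dl, lp = delta_ll_eta(X[g, i], ETA[g, i], LSE[g, i], ph, d)
                lse_p[ci - c0] = lp
                dll += dl
            if math.log(np.random.random()) < dll:
                acc += 1
                beta[g, k] = bp
                L[g, k] = lnew
                for ci in range(c0, c1):
                    i = cells[ci]
                    ph = phi[batch[i], g]
                    x = X[g, i]
                    CUR[g, i] += x * d - (x + ph) * (lse_p[ci - c0] - LSE[g, i])
                    LSE[g, i] = lse_p[ci - c0]
                    ETA[g, i] += d
    return acc, nprop


@njit(cache=True)
def update_p_tau(beta, L, a_p, b_p, a_tau, b_tau):
    """Steps 8-9: conjugate draws of the slab probability p and the spike
    variance tau_beta0^2."""
    G, K = beta.shape
    n1 = 0
    n0 = 0
    ss0 = 0.0
    for g in range(G):
        for k in range(1, K):
            if L[g, k] == 1:
                n1 += 1
            else:
                n0 += 1
                ss0 += beta[g, k] * beta[g, k]
    p = np.random.beta(a_p + n1, b_p + n0)
    tau0 = (b_tau + 0.5 * ss0) / np.random.gamma(a_tau + 0.5 * n0, 1.0)
    return p, tau0


@njit(cache=True)
def build_type_index(W, K):
    """Cells grouped by current type: (order, offsets) with offsets (K+1,)."""
    N = W.shape[0]
    counts = np.zeros(K + 1, dtype=np.int64)
    for i in range(N):
        counts[W[i] + 1] += 1
    off = np.cumsum(counts)
    pos = off[:-1].copy()
    order = np.empty(N, dtype=np.int64)
    for i in range(N):
        order[pos[W[i]]] = i
        pos[W[i]] += 1
    return order, off


@njit(cache=True)
def observed_loglik_kernel(Y, batch, alpha, beta, nu, delta, phi,
                           gamma0, gamma1, pi, nzf):
    """Observed-data log-likelihood, log-sum-exp over cell types per cell."""
    G, N = Y.shape
    K = beta.shape[1]
    total = 0.0
    lp = np.empty(K)
    for i in range(N):
        b = batch[i]
        for k in range(K):
            lp[k] = math.log(pi[b, k]) if pi[b, k] > 0.0 else -1e300
        for g in range(G):
            base = alpha[g] + nu[b, g] + delta[i]
            ph = phi[b, g]
            y = Y[g, i]
            for k in range(K):
                if lp[k] <= -1e299:
                    continue
                mu = math.exp(base + beta[g, k])
                if y == 0:
                    if nzf == 1:
                        lp[k] += ph * math.log(ph / (mu + ph))
                    else:
                        f0, s = zero_branch_masses(mu, ph, gamma0[b], gamma1[b])
                        lp[k] += math.log(f0 + s)
                else:
                    t = nb_logpmf_scalar(y, mu, ph)
                    if nzf == 0:
                        e = gamma0[b] + gamma1[b] * y
                        t += -_softplus(e)
                    lp[k] += t
        m = -1e308
        for k in range(K):
            if lp[k] > m:
                m = lp[k]
        s = 0.0
        for k in range(K):
            if lp[k] > -1e299:
                s += math.exp(lp[k] - m)
        total += m + math.log(s)
    return total
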