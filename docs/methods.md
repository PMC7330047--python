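# Methods

## Model

Observed data are a genes-by-cells matrix of raw counts `Y` collected in
`B` batches with `n_b` cells each, `N = sum(n_b)` cells and `G` genes in
total. The generative hierarchy is

```
Pr(W_bi = k) = pi_bk,                      k = 1..K
X_big | W_bi = k  ~  NB(mu_big, phi_bg),   log mu_big = alpha_g + beta_gk + nu_bg + delta_bi
Z_big | X_big = x ~  Bernoulli(logistic(gamma_b0 + gamma_b1 x))   for x >= 1
Y_big = X_big  if Z_big = 0;   Y_big = 0  if Z_big = 1
```

with NB parameterized so that `Var(X) = mu + mu^2 / phi`. A zero count is
either a biological zero (`X = 0`) or a dropout of a positive count; the
dropout probability decreases with the underlying expression
(`gamma_b1 < 0`), i.e. the missingness is not at random. Identifiability
constraints: `beta_g1 = 0` (baseline type), `nu_1g = 0` (reference batch),
`delta_b1 = 0` for the first cell of each batch.

The observed-data likelihood of one entry mixes the two zero sources:

```
Pr(Y=0)   = f_NB(0; mu, phi) + sum_{x>=1} logistic(g0 + g1 x) f_NB(x; mu, phi)
Pr(Y=y>0) = (1 - logistic(g0 + g1 y)) f_NB(y; mu, phi)
```

and cells mix over types with weights `pi_b`. All likelihood work is done
in log space with log-sum-exp over types. The infinite dropout series is
evaluated by the pmf recurrence `f(x+1) = f(x) (phi+x)/(x+1) mu/(mu+phi)`
with the logistic odds updated multiplicatively, truncated when either the
accumulated NB mass exceeds `1 - 1e-14` (the logistic factor is bounded by
one, so the truncation error is certified below that tail mass) or the
remaining dropout mass — bounded by `logistic(g0 + g1(x+1))` times the
remaining NB mass, the logistic factor being decreasing — falls below
`1e-12` of the accumulated total. The second rule keeps the cost bounded
for large-mean entries whose NB tail stretches far beyond the reach of the
geometrically decaying logistic; the scalar `zero_obs_logprob` entry point
uses only the certified tail rule.

A reduced variant without zero inflation (`variant="nzf"`) replaces both
branches by the plain NB pmf; it shares all machinery via a flag and is
intended for posterior-predictive comparisons of zero rates.

## Priors

Dirichlet(xi) on each `pi_b`; normal priors on `gamma_b0`, `alpha_g`,
`nu_bg`, `delta_bi`; Gamma on `-gamma_b1` (enforcing the sign) and on
`phi_bg`. The cell-type effects carry a spike-and-slab mixture: indicator
`L_gk ~ Bernoulli(p)`, `beta_gk ~ N(0, tau_beta0^2)` under the spike and
`N(0, tau_beta1^2)` under the slab, `p ~ Beta(a_p, b_p)`, `tau_beta0^2 ~
Inv-Gamma(a_tau, b_tau)` with small prior mean, and `tau_beta1^2` fixed
large. A gene with any `L_gk = 1` differs between at least two types — an
intrinsic gene.

Defaults (all overridable through `HyperParameters`): `xi = 1`,
`sigma_z0^2 = 100`, `-gamma_b1 ~ Gamma(1, 1)`, `alpha, nu, delta ~
N(0, 100)`, `phi ~ Gamma(1, 0.1)`, `p ~ Beta(1, 3)`, `tau_beta0^2 ~
Inv-Gamma(2, 0.01)` (prior mean 0.01), `tau_beta1^2 = 100`. These are
weakly informative: prior variances of 100 on log-scale effects are
effectively flat, the spike's prior mean of 0.01 keeps null effects within
±0.2 of zero, and the slab admits log-fold changes of any realistic size.

## Sampler

Metropolis-within-Gibbs with data augmentation; one sweep updates, in
order:

1. `Z` at observed zeros, by a Gibbs draw with the underlying count
   collapsed (Bernoulli with weights: dropout series `S` vs biological-zero
   mass `f_NB(0)`); when an entry turns into a dropout its count is drawn
   exactly by inverse CDF from `p(x) ∝ logistic(g0+g1 x) f_NB(x)`, `x >= 1`,
   using the same recurrence;
2. `X` at dropout entries, by a symmetric integer random walk reflected at
   the lower support bound 1 (the reflection `x' -> 2 - x'` preserves
   proposal symmetry);
3. `W` per cell from its categorical conditional (log-space, terms constant
   across types dropped), followed by a joint (W_i, delta_i) mode jump: a
   cell stuck at a wrong type co-adapts its size factor, so the single-site
   W and delta conditionals both favor the status quo; the move proposes a
   uniformly drawn other type together with the compensating delta shift
   that preserves the cell's expected total count (an involution with unit
   Jacobian plus symmetric jitter, hence a plain posterior ratio);
4. `pi_b ~ Dirichlet(xi + counts)` (conjugate);
5. `(gamma_b0, gamma_b1)` jointly by random-walk Metropolis on the logistic
   regression of `Z` on `X` over entries with `X >= 1` (entries with
   `X = 0` carry no logistic factor in the observed likelihood and are
   excluded), rejecting proposals with `gamma_b1 >= 0`;
6. `alpha_g`, `beta_gk`, `nu_bg`, `delta_bi` by Gaussian random-walk
   Metropolis and `phi_bg` by log-scale random walk, each against its full
   conditional; constrained entries are never touched;
7. joint "group offset" moves: the likelihood is flat along
   "`alpha_g + c` for all g, `delta_i - c` for all cells" except at the
   per-batch anchor cells whose `delta` is pinned at zero (likewise for
   "`nu_bg + c`, `delta_i - c`" within one batch, and for
   "`beta_gk + c` for all g, `delta_i - c` for the cells of type k", where
   the restoring force is the spike-and-slab prior — a coherent shift
   pushes the null genes off zero, which the sampled spike variance would
   otherwise slowly inflate to absorb — plus any pinned anchor cell of that
   type). Single-site walks diffuse along these ridges far too slowly: the
   posterior mean of `delta` can keep batch-wide or type-wide offsets for
   thousands of sweeps. One Metropolis move per batch and per type proposes
   the coordinated shift; only the anchor columns' likelihood changes, so a
   move costs O(G·B);
8. joint `(L_gk, beta_gk)` flips: propose `L' = 1 - L` with a fresh `beta'`
   from the proposed component's prior — the prior and proposal densities
   cancel, leaving the likelihood ratio times the prior odds of `L`;
9. `p ~ Beta(a_p + sum L, b_p + sum(1-L))` (conjugate);
10. `tau_beta0^2` from its inverse-Gamma conditional over spike-assigned
    entries (conjugate).

Proposal scales adapt per parameter toward a 0.3 acceptance rate during
burn-in (Robbins–Monro in log scale, gain `(t+1)^-0.6`) and are frozen
afterwards. Multiple chains receive independent sub-seeds derived from the
user seed; identical inputs give bit-identical draws.

To keep a sweep cheap, per-entry caches of the NB log-likelihood pieces
(linear predictor, `log(exp(eta)+phi)`, the lgamma terms and the entry's
current log pmf) are maintained incrementally across block updates, so a
mean-shift proposal costs one `exp` and one `log` per affected entry and no
lgamma. A test recomputes all caches from scratch after sweeps and checks
agreement.

### Initialization and warm start

The chain is initialized from the data: cell types by k-means on scaled,
per-batch-centered log counts (batch centering because location batch
effects usually dwarf the type effects); `alpha` from per-gene log means of
the nonzero counts; `nu` from batch/reference log-mean ratios; `beta` from
cluster log-mean ratios of batch-adjusted counts; `delta` from log
total-count ratios against the batch's first cell; `phi` by method of
moments (clipped to [0.1, 100]); `gamma = (0, -0.1)`; zeros become
provisional dropouts with probability one half, with a shifted NB draw
filling in the positive count.

Single-site Gibbs on the labels is near-deterministic at these dimensions
— each cell's conditional is dominated by hundreds of genes — so the
sampler keeps whatever partition it starts near and cannot repair a
systematically wrong one. `run_mcmc` therefore warm starts each chain
(deterministically, from the chain's sub-seed): a few dozen sweeps with
labels held fixed let the continuous parameters adapt; then candidate
partitions are generated by k-means on the model-corrected expression
`log1p(X / exp(nu + delta))` over several feature sets, each candidate is
aligned to the current labeling, given empirically re-derived type effects,
adapted for a few sweeps, and scored by the observed-data log-likelihood;
the best-scoring state is kept. Two such stages are run (up to four while
the score still improves materially). The subsequent MCMC has the exact
update structure above; the warm start only chooses where the burn-in
begins. Initialized at the simulation truth the sampler stays there
(stationarity test), and the warm start is what makes that mode reachable
from data alone.

## Posterior summaries and diagnostics

Continuous parameters are estimated by posterior means, cell types by the
per-cell posterior mode, and the underlying count of each observed zero by
the rounded posterior mean of `X` across retained draws (a draw with
`Z = 0` contributes zero), so an entry is called a dropout when its
posterior expected count exceeds one half. `xi_gk = Pr(L_gk = 0 | y)` is
the fraction of retained draws with `L_gk = 0`.

Multiple chains are label-aligned before pooling by optimal assignment
(Hungarian method) on the co-occurrence matrix of posterior-mode labels;
`theta_gk = alpha_g + beta_gk` is permuted and re-anchored so the new
baseline column is zero. Because `L` is defined against the baseline type,
a chain whose alignment moves the baseline is excluded from the `xi` pool
(continuous-parameter pooling is unaffected).

Convergence uses the estimated potential scale reduction
`R = sqrt(((n-1)/n W + B/n) / W)` per scalar, computed for the groups
`theta_gk`, `nu_bg (b >= 2)` and `phi_bg` after label alignment; the run is
declared converged when more than 80% of each group falls below 1.3. The
number of cell types is chosen by

```
BIC(K) = -2 log L_o(theta_hat) + [K(B+G) + 2B + (2B-1)G + sum_b(n_b - 1)] log(N G)
```

minimized over a user range. Intrinsic genes are called by the Bayesian
FDR: candidates for the threshold are the observed `xi` values at most 0.5,
`FDR(kappa) = sum xi 1(xi<=kappa) / sum 1(xi<=kappa)`, and `kappa_0` is the
largest candidate with estimated FDR strictly below the control level
(default 0.05); genes with any called indicator are intrinsic. Dropout
reporting per batch: observed zero rate, the fraction of zeros whose
imputed count is positive, and the posterior-predictive mean zero rate from
replicate datasets simulated at up to 100 evenly spaced retained draws
(a cost-bounded subsample; the estimate is an average of per-replicate
rates either way).

## Batch-effects-corrected counts

Quantile matching with inverse sampling: for each entry, draw `u` uniformly
on `(F_src(x_hat - 1), F_src(x_hat)]` where `F_src` is the CDF of the
entry's fitted NB (with batch and size effects, `F_src(-1) := 0`), and
return the `u`-quantile of the target NB with the same `alpha + beta_w` but
no batch or size effects and the reference batch's overdispersion
`phi_1g`. Drawing `u` uniformly over the interval picks among the several
attainable target integers proportionally to their mass, avoiding the bias
of always taking the minimum or maximum. The half-open interval makes
`u = F_src(x_hat)` attainable, so when source and target distributions
coincide the corrected value equals `x_hat` exactly (a measure-zero
endpoint choice that cannot change the distribution). Entries in the upper
tail are matched in survival-function coordinates (`isf` of the target at
`1 - u` drawn in survival space), because the CDF saturates at 1 in double
precision and would otherwise lose the entry's position entirely.

## Simulator

`build_design` constructs complete, reference-panel, chain-type or custom
batch/type presence patterns and draws compositions as Dirichlet over the
present types; `check_design` builds the batch graph (edge when two batches
share at least two types) and reports connectivity — the identifiability
certificate, given that dropout slopes are negative (condition I), every
type pair differs in at least two genes (condition II, enforced by
resampling in `generate_truth`) and type-effect difference vectors are
distinct across pairs (condition III, which holds almost surely for
continuous draws; an explicit audit is available but off by default).

Default effect sizes emulate multi-batch scRNA-seq at realistic scale:
intrinsic genes take effects from the symmetric grid ±(1.2, 1.6, 2.0, 2.4)
(each non-baseline type affected with probability 0.5), location batch
effects are gene-level normals around batch-wide means cycling through
(0.8, -0.8, 1.6) with sd 0.4 (batch effects comparable to or larger than
type effects), size factors are N(0, 0.5^2) anchored at the first cell per
batch, overdispersions uniform on [2, 6], and dropout intercepts/slopes
uniform on [-0.3, 0.3] and [-0.15, -0.05]. Under these defaults roughly
40–60% of entries are zero and roughly half to three quarters of the zeros
in a batch are dropouts, matching the regime of droplet and plate data.
The generator reproduces the model exactly — it does not emulate read-level
artifacts, UMI collisions, ambient RNA, doublets, or expression continua
within a type, so passing tests demonstrate correct inference under the
model's assumptions, not robustness to their violation.

## Scaled study conditions used by the tests

The test suite and the acceptance script run desk-scale versions of the
model's simulation study (one CPU, minutes instead of hours): a 4-batch
chain-type design with 5 types and batch sizes (120, 120, 80, 80).
Clustering, model-selection and recovery checks use 500 genes
(model selection 300) with well-separated type effects — levels
(2.0, 2.5, 3.0, 3.5), 150 intrinsic genes, and near-uniform compositions
over the types present in each batch. Those three choices preserve the
decision margins of the full-scale setting (3000 genes, 500 intrinsic,
sizable type blocks), which a naive proportional scale-down does not: the
per-cell classification margin shrinks with the absolute number of
intrinsic genes (at the conservative default levels a handful of cells per
dataset are genuinely ambiguous, so no sampler can label all of them
correctly), and the BIC margin for the K-th type — twice the likelihood
gain of splitting it minus (B+G) log(NG) — turns negative when a type
carries few cells or few discriminating genes, making a merged model the
honestly better-scoring one. Measured at G = 300: 150 intrinsic genes give
a 4-vs-5 likelihood gain of ~2200–2600 against the required 1780, while 85
give ~700–800. The FDR experiment keeps the conservative defaults: 50
intrinsic genes among 500, Dirichlet-drawn compositions. Chain lengths:
2000 iterations with 1000 burn-in for the clustering run, 400–600 with
half burn-in elsewhere; the warm start adds a few hundred label-fixed
sweeps.

## Known limitations

- Labels mix poorly across well-separated modes by design of the
  single-site sampler; the warm start mitigates but cannot guarantee the
  global mode on weakly separated data.
- `xi` pooling across chains requires alignments that fix the baseline
  type.
- The BIC count treats `K(B+G) + 2B + (2B-1)G + sum(n_b - 1)` parameters as
  free regardless of the design's presence pattern.
- Corrected counts condition on the point estimates (posterior means and
  modal labels); they do not propagate posterior uncertainty.
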