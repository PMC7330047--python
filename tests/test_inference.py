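import itertools

import numpy as np
import pytest

import zinbatch as zb
from zinbatch.inference import parameter_count, _rhat


class TestAlignLabels:
    def test_identity(self):
        labs = np.array([1, 2, 3, 1, 2, 3])
        assert np.array_equal(zb.align_labels(labs, labs), [1, 2, 3])

    def test_swap_recovered(self):
        ref = np.array([1, 1, 2, 2, 2])
        cand = np.array([2, 2, 1, 1, 1])
        rho = zb.align_labels(ref, cand)
        assert np.array_equal(rho[cand - 1], ref)

    def test_three_class_cooccurrence(self):
        # co-occurrence [[5,0,1],[0,4,0],[2,0,3]]: enumeration over all 6
        # permutations gives the identity assignment, agreement 12/15
        co = np.array([[5, 0, 1], [0, 4, 0], [2, 0, 3]])
        ref, cand = [], []
        for r in range(3):
            for c in range(3):
                ref += [r + 1] * co[r, c]
                cand += [c + 1] * co[r, c]
        best = max(
            itertools.permutations(range(3)),
            key=lambda p: sum(co[p[c], c] for c in range(3)),
        )
        assert best == (0, 1, 2)
        rho = zb.align_labels(np.array(ref), np.array(cand))
        assert np.array_equal(rho, [1, 2, 3])
        agree = (np.array(rho)[np.array(cand) - 1] == np.array(ref)).sum()
        assert agree == 12

    def test_differing_label_counts_padded(self):
        ref = np.array([1, 1, 2, 2, 3, 3])
        cand = np.array([1, 1, 2, 2, 2, 2])
        rho = zb.align_labels(ref, cand)
        assert len(rho) == 2
        assert rho[0] == 1


class TestEpsr:
    def _chains_from_arrays(self, arrays):
        """Wrap raw (T,) scalar chains into minimal ChainSamples for _rhat."""
        return np.stack([a[None, :] if a.ndim == 1 else a for a in arrays])

    def test_hand_computed_value(self):
        # chains (1,2,3,4) and (5,6,7,8): W=5/3, B/n=8, Vhat=0.75*5/3+8
        draws = np.array([[1.0, 2, 3, 4], [5.0, 6, 7, 8]])[:, :, None]
        expected = np.sqrt((0.75 * np.var([1, 2, 3, 4], ddof=1) + 8)
                           / np.var([1, 2, 3, 4], ddof=1))
        assert _rhat(draws)[0] == pytest.approx(expected, abs=1e-12)

    def test_identical_chains_near_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(2000, 3))
        r = _rhat(np.stack([a, a]))
        assert np.all(np.abs(r - 1.0) < 1e-3)

    def test_iid_chains_close_to_one(self):
        rng = np.random.default_rng(1)
        draws = rng.normal(size=(3, 2000, 5))
        assert np.all(np.abs(_rhat(draws) - 1.0) < 0.05)

    def test_single_chain_rejected(self, tiny_sim):
        _, _, data, _ = tiny_sim
        with pytest.raises(ValueError):
            zb.compute_epsr([None])

    def test_two_chain_report(self, tiny_sim):
        _, _, data, _ = tiny_sim
        chains = zb.run_mcmc(data, 2, n_iter=80, burnin=40, seed=6,
                             n_chains=2, warm_start_stages=0)
        rep = zb.compute_epsr(chains)
        assert set(rep.frac_below) == {"theta", "nu", "phi"}
        for v in rep.frac_below.values():
            assert 0.0 <= v <= 1.0
        # R >= sqrt((n-1)/n), the formula's lower bound at zero
        # between-chain variance
        t = chains[0].T
        assert np.all(rep.epsr_theta >= np.sqrt((t - 1) / t) - 1e-9)

    def test_split_chain_epsr_near_one_on_converged_run(self, tiny_sim):
        """Halves of one long stationary chain behave like independent
        chains: split-chain EPSR stays near 1."""
        _, _, data, _ = tiny_sim
        ch = zb.run_mcmc(data, 2, n_iter=900, burnin=300, seed=9)[0]
        half = ch.T // 2
        theta = ch.alpha[:, :, None] + ch.beta
        draws = np.stack([theta[:half], theta[half:2 * half]])
        r = _rhat(draws).ravel()
        assert np.quantile(r, 0.9) < 1.2


class TestBic:
    def test_parameter_count_paper_dimensions(self):
        assert parameter_count(4, 3000, 5, [300, 300, 200, 200]) == 37024

    def test_penalty_log_argument(self):
        # log(sum_b n_b * G) with N*G = 1000 * 3000
        assert np.log(1000 * 3000) == pytest.approx(np.log(3_000_000))

    def test_bic_difference_is_pure_penalty(self):
        n_b = [30, 30]
        c1 = parameter_count(2, 100, 3, n_b)
        c2 = parameter_count(2, 100, 5, n_b)
        assert c2 - c1 == (5 - 3) * (2 + 100)


class TestDetectIntrinsicGenes:
    def test_kappa_search_toy(self):
        xi = np.array([[0.01], [0.2], [0.4], [0.6]])
        genes, kappa0 = zb.detect_intrinsic_genes(xi, alpha=0.05)
        assert kappa0 == pytest.approx(0.01)
        assert np.array_equal(genes, [0])

    def test_all_null_probabilities_zero(self):
        xi = np.zeros((7, 2))
        genes, kappa0 = zb.detect_intrinsic_genes(xi, alpha=0.05)
        assert np.array_equal(genes, np.arange(7))
        assert kappa0 == 0.0

    def test_no_candidate_below_half(self):
        xi = np.full((5, 2), 0.8)
        genes, kappa0 = zb.detect_intrinsic_genes(xi, alpha=0.05)
        assert genes.size == 0 and kappa0 is None

    def test_alpha_validated(self):
        with pytest.raises(ValueError):
            zb.detect_intrinsic_genes(np.zeros((2, 1)), alpha=1.5)

    def test_fdr_estimate_below_alpha_at_kappa0(self):
        rng = np.random.default_rng(0)
        xi = rng.beta(0.3, 3, size=(50, 3))
        genes, kappa0 = zb.detect_intrinsic_genes(xi, alpha=0.1)
        sel = xi[xi <= kappa0]
        assert sel.sum() / sel.size < 0.1


class TestAri:
    def test_identical(self):
        assert zb.adjusted_rand_index([1, 2, 3], [1, 2, 3]) == 1.0

    def test_hand_zero_case(self):
        assert zb.adjusted_rand_index([1, 1, 2, 2], [1, 2, 2, 2]) == pytest.approx(0.0)

    def test_relabel_invariance(self):
        a = np.array([1, 1, 2, 3, 3, 2])
        b = np.array([3, 3, 1, 2, 2, 1])
        assert zb.adjusted_rand_index(a, b) == 1.0

    def test_differing_cluster_counts_allowed(self):
        assert -1 <= zb.adjusted_rand_index([1, 1, 2, 2], [1, 2, 3, 4]) <= 1

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            zb.adjusted_rand_index([1, 2], [1, 2, 3])


class TestSummaries:
    @pytest.fixture(scope="class")
    def short_chain(self, tiny_sim):
        _, _, data, _ = tiny_sim
        return data, zb.run_mcmc(data, 3, n_iter=60, burnin=30, seed=3)[0]

    def test_constant_chain_summary_is_that_draw(self, short_chain):
        data, ch = short_chain
        import copy
        const = copy.copy(ch)
        for name in ("alpha", "beta", "nu", "delta", "phi", "gamma", "pi",
                     "W", "L", "p", "tau0_sq"):
            arr = getattr(ch, name)
            setattr(const, name, np.repeat(arr[:1], arr.shape[0], axis=0))
        fit = zb.summarize_posterior(const)
        assert np.allclose(fit.theta_hat.alpha, ch.alpha[0])
        assert np.array_equal(fit.w_hat, ch.W[0])

    def test_xi_from_l_draws(self):
        # L draws (1,0,1,1) over T=4 -> xi = 0.25
        L = np.array([1, 0, 1, 1], dtype=np.int8).reshape(4, 1, 1)
        xi = (1.0 - L.astype(float)).mean(axis=0)
        assert xi[0, 0] == pytest.approx(0.25)

    def test_w_mode(self):
        draws = np.array([2, 2, 3, 2])
        assert np.bincount(draws, minlength=4)[1:].argmax() + 1 == 2

    def test_x_hat_consistency(self, short_chain):
        data, ch = short_chain
        fit = zb.summarize_posterior(ch)
        nonzero = data.counts > 0
        assert np.array_equal(fit.x_hat[nonzero], data.counts[nonzero])
        assert np.all(fit.x_hat >= 0)

    def test_relabel_invariance_of_pooled_summary(self, short_chain):
        """summarize_posterior after alignment is invariant to a global
        relabeling applied to a chain."""
        import copy
        data, ch = short_chain
        perm = np.array([2, 3, 1])  # cycle the three labels
        sw = copy.copy(ch)
        theta = ch.alpha[:, :, None] + ch.beta
        order = np.argsort(perm - 1)
        theta_p = theta[:, :, order]
        sw.alpha = theta_p[:, :, 0]
        sw.beta = theta_p - sw.alpha[:, :, None]
        sw.W = perm[ch.W - 1].astype(ch.W.dtype)
        sw.pi = ch.pi[:, :, order]
        sw.L = ch.L.copy()
        f1 = zb.summarize_posterior([ch, ch])
        f2 = zb.summarize_posterior([ch, sw])
        th1 = f1.theta_hat.alpha[:, None] + f1.theta_hat.beta
        th2 = f2.theta_hat.alpha[:, None] + f2.theta_hat.beta
        rho = zb.align_labels(f1.w_hat, f2.w_hat)
        assert np.array_equal(rho[f2.w_hat - 1], f1.w_hat)
        assert np.allclose(np.sort(th1, axis=1), np.sort(th2, axis=1), atol=1e-8)


class TestDropoutReport:
    def test_toy_counts(self, tiny_sim):
        _, _, data, _ = tiny_sim
        ch = zb.run_mcmc(data, 2, n_iter=40, burnin=20, seed=4)[0]
        fit = zb.summarize_posterior(ch)
        # toy override: 3 genes x 2 cells, zeros at 4 entries, x_hat > 0 at 2
        toy = zb.ObservedData(counts=[[0, 2], [1, 0], [0, 0]],
                              batch_of_cell=[1, 1])
        fit_toy = zb.FitSummary(
            theta_hat=fit.theta_hat, w_hat=np.array([1, 1]),
            x_hat=np.array([[3, 2], [1, 0], [0, 4]]),
            xi=np.zeros((3, 1)), w_prob=np.ones((2, 2)) / 2,
        )
        rep = zb.dropout_report(toy, fit_toy, ch)
        assert rep.rho0[0] == pytest.approx(4 / 6)
        assert rep.rho_d[0] == pytest.approx(0.5)

    def test_ppc_matches_analytic_zero_probability(self, tiny_sim):
        """Posterior-predictive zero rate agrees with the analytic per-entry
        zero probability averaged over a batch, on a fixed parameter draw."""
        design, params, data, truth = tiny_sim
        import copy
        ch = zb.run_mcmc(data, 3, n_iter=40, burnin=20, seed=4)[0]
        const = copy.copy(ch)
        # pin every stored draw to the simulation truth
        T = ch.T
        const.alpha = np.repeat(params.alpha[None], T, 0)
        const.beta = np.repeat(params.beta[None], T, 0)
        const.nu = np.repeat(params.nu[None], T, 0)
        const.delta = np.repeat(params.delta[None], T, 0)
        const.phi = np.repeat(params.phi[None], T, 0)
        const.gamma = np.repeat(
            np.stack([params.gamma0, params.gamma1], axis=1)[None], T, 0)
        const.W = np.repeat(truth.latent.W[None], T, 0).astype(ch.W.dtype)
        fit = zb.summarize_posterior(const)
        rep = zb.dropout_report(data, fit, const)
        for b in range(data.B):
            cols = np.flatnonzero(data.batch0 == b)
            p0 = np.mean([
                np.exp(zb.zero_obs_logprob(
                    float(np.exp(params.alpha[g] + params.beta[g, truth.latent.W[i] - 1]
                                 + params.nu[b, g] + params.delta[i])),
                    params.phi[b, g], params.gamma0[b], params.gamma1[b]))
                for g in range(0, data.G, 7) for i in cols[::9]
            ])
            assert abs(rep.rho0_ppc[b] - p0) < 0.05
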