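import numpy as np
import pytest

import zinbatch as zb


@pytest.fixture(scope="session")
def tiny_sim():
    """Small 2-batch, 3-type chain-type simulation with known truth."""
    design = zb.build_design("chain_type", 2, 3, [40, 40], seed=101)
    cfg = zb.EffectSizeConfig(n_de_genes=15)
    params = zb.generate_truth(design, 60, cfg, seed=102)
    data, truth = zb.simulate_dataset(params, design, seed=103)
    return design, params, data, truth


@pytest.fixture(scope="session")
def tiny_params():
    """Hand-sized valid parameter set: 5 genes, 6 cells, 2 batches, 2 types."""
    rng = np.random.default_rng(7)
    G, K, B, N = 5, 2, 2, 6
    beta = np.zeros((G, K))
    beta[:, 1] = rng.normal(0, 1, G)
    nu = np.zeros((B, G))
    nu[1] = rng.normal(0.5, 0.5, G)
    delta = rng.normal(0, 0.3, N)
    delta[[0, 3]] = 0.0
    params = zb.ModelParameters(
        alpha=rng.normal(0.5, 0.7, G),
        beta=beta,
        nu=nu,
        delta=delta,
        phi=rng.uniform(1.5, 4.0, (B, G)),
        gamma0=np.array([0.1, -0.2]),
        gamma1=np.array([-0.1, -0.08]),
        pi=np.array([[0.6, 0.4], [0.3, 0.7]]),
    )
    counts = rng.integers(0, 6, size=(G, N))
    counts[:, 0] = 0  # make sure zeros exercise the dropout branch
    data = zb.ObservedData(
        counts=counts, batch_of_cell=np.array([1, 1, 1, 2, 2, 2])
    )
    return data, params
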