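"""Core data containers for multi-batch scRNA-seq count models.

Conventions
-----------
* Count matrices are genes x cells (G x N).
* Batch labels are contiguous integers 1..B; cell-type labels 1..K.
  (Internal sampling kernels use 0-based indices; the conversion happens
  at the module boundary.)
* The first batch is the reference batch (nu[0, :] = 0), the first cell
  type is the baseline type (beta[:, 0] = 0), and the first cell of every
  batch anchors the size factors (delta = 0 there).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ObservedData:
    """A gene-by-cell matrix of raw counts with a batch label per cell.

    Parameters
    ----------
    counts
        (G, N) array of non-negative integers.
    batch_of_cell
        Length-N integer labels, contiguous in 1..B with every batch
        non-empty.
    gene_ids, cell_ids
        Optional identifiers retained for output joins.
    batch_names
        Optional original batch labels, indexed by 1..B.
    """

    counts: np.ndarray
    batch_of_cell: np.ndarray
    gene_ids: list | None = None
    cell_ids: list | None = None
    batch_names: list | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x cells matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            c = np.asarray(self.counts)
            if not np.all(np.isfinite(c)) or np.any(c != np.floor(c)):
                raise ValueError("counts must be non-negative integers")
            self.counts = c.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.batch_of_cell = np.asarray(self.batch_of_cell, dtype=np.int64)
        if self.batch_of_cell.shape != (self.counts.shape[1],):
            raise ValueError("batch_of_cell must have one label per cell")
        labels = np.unique(self.batch_of_cell)
        if labels.size == 0 or labels[0] != 1 or not np.array_equal(
            labels, np.arange(1, labels.size + 1)
        ):
            raise ValueError(
                "batch labels must be contiguous 1..B with every batch non-empty"
            )

    @property
    def G(self) -> int:
        return self.counts.shape[0]

    @property
    def N(self) -> int:
        return self.counts.shape[1]

    @property
    def B(self) -> int:
        return int(self.batch_of_cell.max())

    @property
    def n_b(self) -> np.ndarray:
        """Per-batch cell counts."""
        return np.bincount(self.batch_of_cell - 1, minlength=self.B)

    @property
    def batch0(self) -> np.ndarray:
        """0-based batch index per cell (kernel convention)."""
        return self.batch_of_cell - 1

    def anchor_cells(self) -> np.ndarray:
        """Index of the first cell of each batch (size-factor anchors)."""
        first = np.full(self.B, -1, dtype=np.int64)
        for i, b in enumerate(self.batch0):
            if first[b] < 0:
                first[b] = i
        return first


@dataclass
class ModelParameters:
    """Parameters Theta of the zero-inflated NB batch model.

    log(mu_big) = alpha_g + beta_g,W(bi) + nu_bg + delta_bi and the
    dropout probability of a positive count x is
    logistic(gamma0_b + gamma1_b * x) with gamma1_b < 0.
    """

    alpha: np.ndarray          # (G,)
    beta: np.ndarray           # (G, K), beta[:, 0] == 0
    nu: np.ndarray             # (B, G), nu[0, :] == 0
    delta: np.ndarray          # (N,), zero at the first cell of each batch
    phi: np.ndarray            # (B, G), > 0
    gamma0: np.ndarray         # (B,)
    gamma1: np.ndarray         # (B,), < 0
    pi: np.ndarray             # (B, K), rows on the simplex

    def __post_init__(self):
        for name in ("alpha", "beta", "nu", "delta", "phi", "gamma0", "gamma1", "pi"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))

    @property
    def G(self) -> int:
        return self.alpha.shape[0]

    @property
    def K(self) -> int:
        return self.beta.shape[1]

    @property
    def B(self) -> int:
        return self.nu.shape[0]

    def validate(self, anchors: np.ndarray | None = None) -> None:
        """Check the identifiability constraints; raise ValueError on breach."""
        G, K, B = self.G, self.K, self.B
        if self.beta.shape != (G, K) or self.nu.shape != (B, G):
            raise ValueError("inconsistent parameter dimensions")
        if self.phi.shape != (B, G) or self.pi.shape != (B, K):
            raise ValueError("inconsistent parameter dimensions")
        if np.any(self.beta[:, 0] != 0):
            raise ValueError("beta[:, 0] must be zero (baseline cell type)")
        if np.any(self.nu[0, :] != 0):
            raise ValueError("nu[0, :] must be zero (reference batch)")
        if np.any(self.phi <= 0):
            raise ValueError("phi must be positive")
        if np.any(self.gamma1 >= 0):
            raise ValueError("gamma1 must be negative in every batch (condition I)")
        if not np.allclose(self.pi.sum(axis=1), 1.0, atol=1e-8) or np.any(self.pi < 0):
            raise ValueError("each row of pi must lie on the probability simplex")
        if anchors is not None and np.any(self.delta[anchors] != 0):
            raise ValueError("delta must be zero at the first cell of each batch")


@dataclass
class LatentState:
    """Latent variables: underlying counts, dropout flags, labels, DE state.

    Z == 1 only where the observed count is zero but the underlying count
    is positive; wherever Z == 0 the observed count equals X.
    """

    X: np.ndarray              # (G, N) underlying counts
    Z: np.ndarray              # (G, N) dropout indicators in {0, 1}
    W: np.ndarray              # (N,) cell-type labels in 1..K
    L: np.ndarray | None = None    # (G, K-1) DE indicators vs. type 1
    p: float = 0.5                  # slab probability
    tau_beta0_sq: float = 0.01      # spike variance

    def check_consistency(self, Y: np.ndarray) -> None:
        Z = np.asarray(self.Z)
        X = np.asarray(self.X)
        if np.any((Z == 1) & ((Y != 0) | (X <= 0))):
            raise ValueError("Z=1 requires Y=0 and X>0")
        if np.any((Z == 0) & (X != Y)):
            raise ValueError("Y must equal X wherever Z=0")


@dataclass
class SimulationTruth:
    """Ground truth bundled with a simulated dataset."""

    params: ModelParameters
    latent: LatentState
    de_gene_set: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
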