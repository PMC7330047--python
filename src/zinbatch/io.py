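"""Readers and writers for the formats the tool touches.

Counts travel as MatrixMarket MTX (genes x cells) or delimited text with a
header; cell metadata as a delimited table with a `batch` column. Readers
validate rather than coerce: fractional or negative counts and missing
batch labels are rejected with row/column context. Batch labels of any type
are re-indexed to contiguous 1..B in order of first appearance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .data import ObservedData


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep)


def read_counts(path, metadata_path) -> ObservedData:
    """Load a counts matrix plus per-cell metadata into ObservedData.

    The metadata row order must match the cell (column) order of the
    counts. A `cell` column, when present, is kept as cell identifiers.
    """
    path = Path(path)
    metadata_path = Path(metadata_path)
    gene_ids = None
    cell_ids = None

    if path.suffix.lower() in (".mtx", ".mm"):
        mat = spio.mmread(path)
        counts = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
    else:
        df = _read_table(path)
        first = df.columns[0]
        if not np.issubdtype(df[first].dtype, np.number):
            df = df.set_index(first)
            gene_ids = list(df.index)
        cell_ids = list(df.columns)
        counts = df.to_numpy()

    if counts.ndim != 2:
        raise ValueError(f"{path}: counts must be a 2-D matrix")
    bad = ~np.isfinite(counts) | (counts < 0) | (counts != np.floor(counts))
    if bad.any():
        g, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: invalid count at gene row {g + 1}, cell column {c + 1} "
            f"(value {counts[g, c]!r}); counts must be non-negative integers"
        )
    counts = counts.astype(np.int64)

    meta = _read_table(metadata_path)
    if "batch" not in meta.columns:
        raise ValueError(f"{metadata_path}: metadata needs a 'batch' column")
    if meta["batch"].isna().any():
        row = int(meta["batch"].isna().idxmax())
        raise ValueError(f"{metadata_path}: missing batch label at row {row + 1}")
    if len(meta) != counts.shape[1]:
        raise ValueError(
            f"metadata has {len(meta)} rows but counts has "
            f"{counts.shape[1]} cells"
        )
    raw = meta["batch"].tolist()
    order = list(dict.fromkeys(raw))          # first-appearance order
    mapping = {lab: i + 1 for i, lab in enumerate(order)}
    batch = np.array([mapping[lab] for lab in raw], dtype=np.int64)
    if "cell" in meta.columns:
        cell_ids = meta["cell"].tolist()

    return ObservedData(counts=counts, batch_of_cell=batch,
                        gene_ids=gene_ids, cell_ids=cell_ids,
                        batch_names=order)


def write_counts_mtx(path, counts: np.ndarray, comment: str = ""):
    spio.mmwrite(str(path), sparse.coo_matrix(np.asarray(counts)),
                 comment=comment, field="integer")


def write_cell_metadata(path, data: ObservedData, true_type=None):
    df = pd.DataFrame({
        "cell": data.cell_ids or [f"cell{i + 1}" for i in range(data.N)],
        "batch": data.batch_of_cell,
    })
    if true_type is not None:
        df["true_type"] = np.asarray(true_type)
    df.to_csv(path, sep="\t", index=False)


def write_truth_bundle(path, truth):
    """Ground-truth parameters and latent state as a key-value container."""
    p = truth.params
    np.savez_compressed(
        path, alpha=p.alpha, beta=p.beta, nu=p.nu, delta=p.delta, phi=p.phi,
        gamma0=p.gamma0, gamma1=p.gamma1, pi=p.pi,
        X=truth.latent.X, Z=truth.latent.Z, W=truth.latent.W,
        de_gene_set=truth.de_gene_set,
    )


def write_chain(path, samples):
    """One array container per parameter block plus run metadata."""
    np.savez_compressed(
        path, alpha=samples.alpha, beta=samples.beta, nu=samples.nu,
        delta=samples.delta, phi=samples.phi, gamma=samples.gamma,
        pi=samples.pi, W=samples.W, L=samples.L, p=samples.p,
        tau0_sq=samples.tau0_sq, sum_x_dropout=samples.sum_x_dropout,
        cnt_dropout=samples.cnt_dropout, ppc_zero_rates=samples.ppc_zero_rates,
    )


def write_manifest(path, command: str, config: dict, extras: dict | None = None):
    """Run manifest sufficient to re-run the command identically."""
    from . import __version__

    payload = {
        "command": command,
        "version": __version__,
        "config": config,
    }
    if extras:
        payload.update(extras)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    Path(path).write_text(json.dumps(payload, indent=2, default=default))


def write_fit_summary(outdir, data: ObservedData, fit):
    """Cell-assignment, intrinsic-gene and parameter tables."""
    outdir = Path(outdir)
    cells = pd.DataFrame({
        "cell": data.cell_ids or [f"cell{i + 1}" for i in range(data.N)],
        "batch": data.batch_of_cell,
        "w_hat": fit.w_hat,
    })
    for k in range(fit.K):
        cells[f"prob_type{k + 1}"] = fit.w_prob[:, k]
    cells.to_csv(outdir / "cell_assignments.tsv", sep="\t", index=False)

    genes = pd.DataFrame({
        "gene": data.gene_ids or [f"gene{g + 1}" for g in range(data.G)],
    })
    for k in range(fit.xi.shape[1]):
        genes[f"xi_type{k + 2}"] = fit.xi[:, k]
    if fit.intrinsic_genes is not None:
        called = np.zeros(data.G, dtype=int)
        called[fit.intrinsic_genes] = 1
        genes["intrinsic"] = called
    genes.to_csv(outdir / "intrinsic_genes.tsv", sep="\t", index=False)
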