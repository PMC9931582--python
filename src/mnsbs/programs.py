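"""Gene-program analysis by NMF with cross-dataset transfer evaluation.

Expression is normalised to logTPM (natural log of counts per million plus
a pseudocount of 1) and factorised as A ~ W H^T with non-negative cell
loadings W (cells x K) and gene loadings H (genes x K), K = 15 by default.
Transferability of programs between datasets sharing a gene universe is
scored by fixing one model's gene loadings, projecting cell loadings on
the other dataset by non-negative least squares, and measuring the mean
squared reconstruction error — compared between the dataset's own model
(self), the other dataset's model (cross), and a model fit on expression
with each gene's values scrambled across cells (null).  Consensus NMF
pools factors from many random restarts, clusters their L2-normalised
gene-loading vectors, drops outliers, and takes component-wise medians.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.cluster import KMeans
from sklearn.decomposition import NMF

__all__ = [
    "lognormalize",
    "NmfModel",
    "fit_nmf",
    "project",
    "permute_within_gene",
    "transfer_eval",
    "TransferReport",
    "consensus_nmf",
    "ConsensusModel",
    "factor_correlation",
]


def lognormalize(
    counts: pd.DataFrame, scale: float = 1e6, min_cell_frac: float = 0.01
) -> Tuple[pd.DataFrame, pd.Series]:
    """logTPM transform: ln(1 + scale * count / cell_total), per cell.

    Returns the transformed matrix and a boolean gene filter marking genes
    expressed (nonzero) in more than ``min_cell_frac`` of cells.  Cells with
    zero total raise ValueError listing them.
    """
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    totals = mat.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"cells with zero total counts: {list(counts.index[zero])}")
    logtpm = np.log1p(scale * mat / totals[:, None])
    gene_filter = pd.Series(
        (mat > 0).mean(axis=0) > min_cell_frac, index=counts.columns
    )
    return pd.DataFrame(logtpm, index=counts.index, columns=counts.columns), gene_filter


@dataclass
class NmfModel:
    """Non-negative factorisation A ~ cell_loadings @ gene_loadings.T."""

    gene_loadings: pd.DataFrame  # genes x K
    cell_loadings: pd.DataFrame  # cells x K
    k: int
    seed: int
    reconstruction_err: float

    def reconstruct(self) -> np.ndarray:
        return self.cell_loadings.to_numpy() @ self.gene_loadings.to_numpy().T


def fit_nmf(expr: pd.DataFrame, k: int = 15, seed: int = 0, max_iter: int = 400) -> NmfModel:
    """Fit NMF by coordinate descent; deterministic for a fixed seed."""
    if k > min(expr.shape):
        raise ValueError(f"k={k} exceeds matrix dimensions {expr.shape}")
    nmf = NMF(
        n_components=k, init="random", random_state=seed, max_iter=max_iter,
        tol=1e-5,
    )
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        W = nmf.fit_transform(expr.to_numpy())
    H = nmf.components_
    cols = [f"factor_{i+1}" for i in range(k)]
    return NmfModel(
        gene_loadings=pd.DataFrame(H.T, index=expr.columns, columns=cols),
        cell_loadings=pd.DataFrame(W, index=expr.index, columns=cols),
        k=k,
        seed=seed,
        reconstruction_err=float(nmf.reconstruction_err_),
    )


def _nnls_rows(basis: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Solve min ||basis @ x - t||, x >= 0 for each column t of targets."""
    out = np.empty((targets.shape[1], basis.shape[1]))
    for j in range(targets.shape[1]):
        out[j], _ = nnls(basis, targets[:, j])
    return out


def project(
    loadings: pd.DataFrame, data: pd.DataFrame, direction: str = "onto_cells"
) -> pd.DataFrame:
    """Complementary loadings by per-row non-negative least squares.

    ``onto_cells``: given gene loadings (genes x K), solve cell loadings for
    each cell of ``data`` (cells x genes).  ``onto_genes``: given cell
    loadings (cells x K), solve gene loadings for each gene column.
    """
    cols = loadings.columns
    if direction == "onto_cells":
        basis = loadings.to_numpy()  # genes x K
        targets = data.to_numpy().T  # genes x cells
        sol = _nnls_rows(basis, targets)  # cells x K
        return pd.DataFrame(sol, index=data.index, columns=cols)
    if direction == "onto_genes":
        basis = loadings.to_numpy()  # cells x K
        targets = data.to_numpy()  # cells x genes
        sol = _nnls_rows(basis, targets)  # genes x K
        return pd.DataFrame(sol, index=data.columns, columns=cols)
    raise ValueError(f"unknown direction {direction!r}")


def permute_within_gene(expr: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Scramble each gene's values across cells independently."""
    rng = np.random.default_rng(seed)
    mat = expr.to_numpy().copy()
    for j in range(mat.shape[1]):
        rng.shuffle(mat[:, j])
    return pd.DataFrame(mat, index=expr.index, columns=expr.columns)


def _mse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean((a - b) ** 2))


def _recon_mse(gene_loadings: pd.DataFrame, data: pd.DataFrame) -> float:
    """MSE of reconstructing ``data`` with gene loadings fixed (cells projected)."""
    W = project(gene_loadings, data, "onto_cells").to_numpy()
    return _mse(W @ gene_loadings.to_numpy().T, data.to_numpy())


@dataclass
class TransferReport:
    """Per-direction, per-loading-kind MSEs over repeated random splits."""

    records: pd.DataFrame  # columns: repeat, direction, kind, mse_self, mse_cross, mse_null

    def summary(self) -> pd.DataFrame:
        return (
            self.records.groupby(["direction", "kind"])[
                ["mse_self", "mse_cross", "mse_null"]
            ]
            .agg(["mean", "std"])
        )


def transfer_eval(
    dataA: pd.DataFrame,
    dataB: pd.DataFrame,
    k: int = 15,
    train_n: int = 5000,
    n_repeat: int = 10,
    seed: int = 0,
) -> TransferReport:
    """Cross-dataset NMF transfer with a permuted null.

    Per repeat, each dataset is split into a training set of ``train_n``
    cells and a held-out test set; models are fit on each training set and
    on a within-gene-permuted copy of the *other* dataset's training set.
    Gene-loading quality is the MSE of reconstructing a dataset's training
    matrix with gene loadings fixed; cell-loading quality is the same MSE
    on the held-out test matrix.
    """
    if min(len(dataA), len(dataB)) <= train_n:
        raise ValueError("both datasets must exceed train_n cells")
    rows = []
    for r in range(n_repeat):
        parts = {}
        for label, data in (("A", dataA), ("B", dataB)):
            # per-dataset RNG with a common seed: identical inputs give
            # identical splits (and hence mse_cross == mse_self exactly)
            rng = np.random.default_rng(seed + r)
            idx = rng.permutation(len(data))
            parts[label] = (
                data.iloc[idx[:train_n]],
                data.iloc[idx[train_n:]],
            )
        models = {
            label: fit_nmf(parts[label][0], k=k, seed=seed + r)
            for label in ("A", "B")
        }
        null_models = {
            label: fit_nmf(
                permute_within_gene(parts[label][0], seed=seed + r), k=k, seed=seed + r
            )
            for label in ("A", "B")
        }
        for src, dst in (("A", "B"), ("B", "A")):
            train_dst, test_dst = parts[dst]
            for kind, target in (("gene", train_dst), ("cell", test_dst)):
                rows.append(
                    {
                        "repeat": r,
                        "direction": f"{src}->{dst}",
                        "kind": kind,
                        "mse_self": _recon_mse(models[dst].gene_loadings, target),
                        "mse_cross": _recon_mse(models[src].gene_loadings, target),
                        "mse_null": _recon_mse(
                            null_models[dst].gene_loadings, target
                        ),
                    }
                )
    return TransferReport(pd.DataFrame(rows))


@dataclass
class ConsensusModel:
    """Consensus over many NMF restarts (cNMF-style aggregation)."""

    gene_loadings: pd.DataFrame  # genes x K (cluster medians, L2-normalised input)
    cell_loadings: pd.DataFrame  # cells x K (refit by projection)
    stability: pd.DataFrame  # per factor: cluster_size, mean_within_corr
    k: int
    n_runs: int


def consensus_nmf(
    expr: pd.DataFrame,
    k: int = 15,
    n_runs: int = 100,
    seed: int = 0,
    outlier_quantile: float = 0.9,
    variable_genes: Optional[Sequence[str]] = None,
    max_iter: int = 300,
) -> ConsensusModel:
    """Consensus NMF: pool factors over restarts, cluster, take medians.

    Gene-loading vectors from ``n_runs`` seeded restarts are L2-normalised
    and clustered with k-means into ``k`` groups; factors whose distance to
    their centroid exceeds the ``outlier_quantile`` of all distances are
    dropped; consensus gene loadings are per-cluster component-wise
    medians, and cell loadings are refit by NNLS projection.  When
    ``variable_genes`` is given the factorisation runs on that subset (the
    externally supplied variable-gene list), and consensus loadings are
    reported on it.
    """
    X = expr if variable_genes is None else expr.loc[:, list(variable_genes)]
    factors = []
    run_of = []
    for i in range(n_runs):
        m = fit_nmf(X, k=k, seed=seed + i, max_iter=max_iter)
        H = m.gene_loadings.to_numpy().T  # K x genes
        factors.append(H)
        run_of.extend([i] * k)
    F = np.vstack(factors)  # (n_runs*k) x genes
    norms = np.linalg.norm(F, axis=1)
    norms[norms == 0] = 1.0
    Fn = F / norms[:, None]

    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(Fn)
    dists = np.linalg.norm(Fn - km.cluster_centers_[labels], axis=1)
    cutoff = np.quantile(dists, outlier_quantile)
    ok = dists <= cutoff
    kept_clusters = np.unique(labels[ok])
    if len(kept_clusters) < k:
        raise ValueError(
            f"only {len(kept_clusters)} non-outlier clusters for k={k}; "
            "consider a lower k"
        )

    cols = [f"factor_{i+1}" for i in range(k)]
    H_cons = np.empty((k, Fn.shape[1]))
    stab_rows = []
    for ci, c in enumerate(sorted(kept_clusters)):
        members = Fn[ok & (labels == c)]
        H_cons[ci] = np.median(members, axis=0)
        if len(members) > 1:
            C = np.corrcoef(members)
            mean_corr = float(C[np.triu_indices(len(members), 1)].mean())
        else:
            mean_corr = 1.0
        stab_rows.append(
            {"factor": cols[ci], "cluster_size": len(members),
             "mean_within_corr": mean_corr}
        )
    gene_loadings = pd.DataFrame(H_cons.T, index=X.columns, columns=cols)
    cell_loadings = project(gene_loadings, X, "onto_cells")
    return ConsensusModel(
        gene_loadings=gene_loadings,
        cell_loadings=cell_loadings,
        stability=pd.DataFrame(stab_rows).set_index("factor"),
        k=k,
        n_runs=n_runs,
    )


def factor_correlation(
    A: pd.DataFrame, B: pd.DataFrame, kind: str = "gene"
) -> pd.DataFrame:
    """K x K Pearson correlation between factor loadings of two models.

    ``A`` and ``B`` are loading frames (genes x K or cells x K) sharing
    their row universe.  Constant factors give NaN rows/columns.
    """
    if not A.index.equals(B.index):
        raise ValueError(f"{kind} loadings must share their row universe")
    a = A.to_numpy()
    b = B.to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(a.T, b.T)[: a.shape[1], a.shape[1]:]
    return pd.DataFrame(C, index=A.columns, columns=B.columns)
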