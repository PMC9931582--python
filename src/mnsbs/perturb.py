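"""Permutation-calibrated elastic-net estimation of CRISPR guide effects.

In a Perturb-Seq experiment each cell carries one guide (perturbation),
one hash label (sample of origin) and a cluster label.  Per-gene expression
(logTPM) is modelled as a linear function of a covariate matrix — scaled
UMI count plus one-hot guide, hash and cluster blocks — fit with an
elastic net (l1_ratio 0.5, alpha 5e-4).  Significance is calibrated with a
margin-preserving permutation null: guide labels are shuffled within each
hash stratum (preserving the guide x hash contingency margins), the model
is refit, each gene is scored by its maximum absolute guide coefficient,
and empirical p-values are computed within 20 equal-size mean-expression
bins.  Guide similarity is the Pearson correlation between guide
coefficient vectors over the significant genes.

The workflow is exposed statsmodels-style: build a
:class:`GuideEffectModel` from expression + metadata, call ``fit()`` to get
a :class:`GuideEffectResults` carrying coefficients, permutation null,
p-values and the similarity matrix.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet

__all__ = [
    "filter_cells_genes",
    "build_design",
    "fit_effects",
    "permute_guides",
    "gene_scores",
    "empirical_pvalues",
    "guide_similarity",
    "GuideEffectModel",
    "GuideEffectResults",
]

HYPERPARAMS = {"l1_ratio": 0.5, "alpha": 0.0005, "max_iter": 10000}


def _single_label(series: pd.Series) -> pd.Series:
    """True where the label is a single assignment (not missing/multiple)."""
    s = series.astype(object)
    bad = s.isna() | s.isin(["", "multiple", "Multiplet", "unassigned"])
    return ~bad


def filter_cells_genes(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    min_cells_per_guide: int = 11,
    min_gene_frac: float = 0.05,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the cell and gene retention rules.

    Cells must have exactly one guide and one hash assignment; guides with
    fewer than ``min_cells_per_guide`` cells are dropped along with their
    cells; genes must be expressed (nonzero) in more than ``min_gene_frac``
    of the retained cells.
    """
    if len(expr) != len(meta):
        raise ValueError("expr rows must match meta rows")
    keep = _single_label(meta["guide"]) & _single_label(meta["hash"])
    meta = meta[keep.to_numpy()]
    expr = expr.loc[meta.index]
    sizes = meta["guide"].value_counts()
    good_guides = sizes[sizes >= min_cells_per_guide].index
    keep2 = meta["guide"].isin(good_guides)
    meta = meta[keep2.to_numpy()]
    expr = expr.loc[meta.index]
    if meta.empty:
        raise ValueError("no cells survive filtering")
    frac = (expr > 0).mean(axis=0)
    expr = expr.loc[:, frac > min_gene_frac]
    return expr, meta


def build_design(meta: pd.DataFrame) -> pd.DataFrame:
    """Covariate matrix: z-scored UMI count + one-hot guide/hash/cluster.

    One-hot blocks are complete (no reference level dropped); the ridge
    component of the elastic net handles the collinearity.
    """
    n_umis = meta["n_umis"].astype(float)
    sd = n_umis.std(ddof=0)
    scaled = (n_umis - n_umis.mean()) / (sd if sd > 0 else 1.0)
    parts = [scaled.rename("n_umis_scaled").to_frame()]
    for col, prefix in [("guide", "guide"), ("hash", "hash"), ("cluster", "cluster")]:
        onehot = pd.get_dummies(meta[col].astype(str), prefix=prefix, dtype=float)
        parts.append(onehot)
    X = pd.concat(parts, axis=1)
    X.index = meta.index
    return X


def fit_effects(
    Y: pd.DataFrame,
    X: pd.DataFrame,
    l1_ratio: float = HYPERPARAMS["l1_ratio"],
    alpha: float = HYPERPARAMS["alpha"],
    max_iter: int = HYPERPARAMS["max_iter"],
) -> pd.DataFrame:
    """Per-gene elastic-net coefficients (genes x covariates).

    Minimises (1/2n)||y - Xb - b0||^2 + alpha*(rho*||b||_1 +
    (1-rho)/2*||b||_2^2) with an unpenalised intercept, independently per
    gene.  Non-convergence warns but coefficients are still returned.
    """
    model = ElasticNet(
        l1_ratio=l1_ratio, alpha=alpha, max_iter=max_iter, fit_intercept=True
    )
    with warnings.catch_warnings():
        warnings.simplefilter("always", ConvergenceWarning)
        model.fit(X.to_numpy(), Y.to_numpy())
    coef = model.coef_
    if coef.ndim == 1:
        coef = coef[None, :]
    return pd.DataFrame(coef, index=Y.columns, columns=X.columns)


def permute_guides(
    meta: pd.DataFrame, n_perm: int = 100, seed: int = 0
) -> List[np.ndarray]:
    """Guide-label permutations that shuffle within each hash stratum.

    Shuffling within strata leaves the guide x hash contingency margins of
    every permutation identical to the observed table.
    """
    rng = np.random.default_rng(seed)
    guides = meta["guide"].to_numpy(dtype=object)
    hashes = meta["hash"].to_numpy(dtype=object)
    strata = {h: np.flatnonzero(hashes == h) for h in pd.unique(hashes)}
    perms = []
    for _ in range(n_perm):
        out = guides.copy()
        for idx in strata.values():
            out[idx] = guides[idx][rng.permutation(len(idx))]
        perms.append(out)
    return perms


def gene_scores(effects: pd.DataFrame, guide_cols: Sequence[str]) -> pd.Series:
    """Score each gene by max |coefficient| over targeting-guide columns."""
    return effects[list(guide_cols)].abs().max(axis=1)


@dataclass
class GeneScorePValue:
    gene: str
    score: float
    expression_bin: int
    p: float


def empirical_pvalues(
    observed: pd.Series,
    null_scores: np.ndarray,
    mean_expr: pd.Series,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Expression-binned empirical p-values against the permutation null.

    Genes are ranked by mean expression into ``n_bins`` bins of equal size;
    for each gene, p = (1 + #{null scores in its bin >= observed}) /
    (1 + total null scores in its bin), pooling all permutations
    (add-one convention, so p > 0).

    ``null_scores`` has shape (n_perm, n_genes), gene order matching
    ``observed``.
    """
    genes = observed.index
    order = np.argsort(mean_expr.loc[genes].to_numpy(), kind="stable")
    bin_of = np.empty(len(genes), dtype=int)
    for b, idx in enumerate(np.array_split(order, n_bins)):
        bin_of[idx] = b
    obs = observed.to_numpy()
    pvals = np.empty(len(genes))
    for b in range(n_bins):
        members = np.flatnonzero(bin_of == b)
        if members.size == 0:
            continue
        null_pool = np.sort(null_scores[:, members].ravel())
        n_null = null_pool.size
        ge = n_null - np.searchsorted(null_pool, obs[members], side="left")
        pvals[members] = (1.0 + ge) / (1.0 + n_null)
    return pd.DataFrame(
        {"score": obs, "expression_bin": bin_of + 1, "p": pvals}, index=genes
    )


def guide_similarity(
    effects: pd.DataFrame,
    pvalues: pd.DataFrame,
    guide_cols: Sequence[str],
    p_thresh: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation between guide coefficient vectors.

    Restricted to targeting-guide columns and genes with p < ``p_thresh``.
    Zero-variance guide columns yield NaN for their pairs.
    """
    sig = pvalues.index[pvalues["p"] < p_thresh]
    if len(sig) < 2:
        raise ValueError("fewer than 2 significant genes; similarity undefined")
    M = effects.loc[sig, list(guide_cols)].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = M.std(axis=0)
        C = np.corrcoef(M, rowvar=False)
    C = np.atleast_2d(C)
    C[sd == 0, :] = np.nan
    C[:, sd == 0] = np.nan
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=list(guide_cols), columns=list(guide_cols))


# ---------------------------------------------------------------------------
# model / results surface

class GuideEffectModel:
    """Elastic-net guide-effect model over filtered Perturb-Seq data.

    Parameters
    ----------
    expr : cells x genes logTPM frame (pre-filtering; the retention rules
        are applied at construction).
    meta : per-cell frame with columns guide, hash, cluster, n_umis.
    control_guides : guide labels treated as non-targeting controls and
        excluded from scoring and similarity.
    """

    def __init__(
        self,
        expr: pd.DataFrame,
        meta: pd.DataFrame,
        control_guides: Sequence[str] = (),
        min_cells_per_guide: int = 11,
        min_gene_frac: float = 0.05,
    ):
        self.Y, self.meta = filter_cells_genes(
            expr, meta, min_cells_per_guide, min_gene_frac
        )
        self.X = build_design(self.meta)
        self.control_guides = set(control_guides)
        self.guide_cols = [
            c
            for c in self.X.columns
            if c.startswith("guide_")
            and c[len("guide_"):] not in self.control_guides
        ]

    @classmethod
    def from_files(cls, expr_path, meta_path, **kw) -> "GuideEffectModel":
        expr = pd.read_csv(expr_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(expr, meta.loc[expr.index], **kw)

    def fit(self, **hyper) -> "GuideEffectResults":
        effects = fit_effects(self.Y, self.X, **hyper)
        return GuideEffectResults(self, effects)


class GuideEffectResults:
    """Fitted coefficients plus permutation-based inference."""

    def __init__(self, model: GuideEffectModel, effects: pd.DataFrame):
        self.model = model
        self.effects = effects
        self.null_scores: Optional[np.ndarray] = None
        self._pvalues: Optional[pd.DataFrame] = None

    @property
    def scores(self) -> pd.Series:
        return gene_scores(self.effects, self.model.guide_cols)

    def run_permutations(self, n_perm: int = 100, seed: int = 0, **hyper) -> np.ndarray:
        """Refit under margin-preserving guide permutations; store null scores."""
        m = self.model
        perms = permute_guides(m.meta, n_perm=n_perm, seed=seed)
        null = np.empty((n_perm, self.effects.shape[0]))
        for i, labels in enumerate(perms):
            meta_p = m.meta.copy()
            meta_p["guide"] = labels
            Xp = build_design(meta_p)[m.X.columns]
            eff_p = fit_effects(m.Y, Xp, **hyper)
            null[i] = gene_scores(eff_p, m.guide_cols).to_numpy()
        self.null_scores = null
        return null

    def pvalues(self, n_bins: int = 20) -> pd.DataFrame:
        if self.null_scores is None:
            raise RuntimeError("call run_permutations() first")
        if self._pvalues is None:
            self._pvalues = empirical_pvalues(
                self.scores, self.null_scores, self.model.Y.mean(axis=0), n_bins
            )
        return self._pvalues

    def guide_similarity(self, p_thresh: float = 0.05) -> pd.DataFrame:
        return guide_similarity(
            self.effects, self.pvalues(), self.model.guide_cols, p_thresh
        )

    def summary(self) -> str:
        m = self.model
        lines = [
            "Guide effect model (elastic net, permutation-calibrated)",
            "=" * 56,
            f"cells: {len(m.meta)}   genes: {m.Y.shape[1]}   "
            f"covariates: {m.X.shape[1]}",
            f"targeting guides: {len(m.guide_cols)}   "
            f"controls excluded: {len(m.control_guides)}",
        ]
        if self.null_scores is not None:
            pv = self.pvalues()
            lines.append(
                f"permutations: {self.null_scores.shape[0]}   "
                f"genes with p<0.05: {(pv['p'] < 0.05).sum()}"
            )
        top = self.scores.sort_values(ascending=False).head(5)
        lines.append("top genes by |max guide coefficient|:")
        for g, s in top.items():
            lines.append(f"  {g}: {s:.4f}")
        return "\n".join(lines)
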