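"""Gene filtering, sum standardization and optional sample reduction.

Filtering removes genes whose raw signal intensity (row-vector norm) lies
in the extreme tails of the intensity distribution: the weakest genes are
noise-dominated and the strongest are outlier-prone, and both distort the
scatter-simplex geometry.  Sum standardization then maps each surviving
gene vector onto the unit-sum simplex in sample space, where mixing
proportions become simplex vertices.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .io import ExpressionMatrix

logger = logging.getLogger("camix")


@dataclasses.dataclass
class GeneVectorSet:
    """Sum-standardized gene vectors lying on the unit-sum simplex."""

    gene_ids: list
    vectors: np.ndarray  # (n_genes, n_samples), rows sum to 1
    raw_ref: ExpressionMatrix | None = None

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if np.any(self.vectors < 0):
            raise ValueError("gene vectors must be non-negative")
        if not np.allclose(self.vectors.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("gene vectors must sum to 1")

    @property
    def n_genes(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_samples(self) -> int:
        return self.vectors.shape[1]


def gene_norms(expr: ExpressionMatrix, norm: str = "l2") -> np.ndarray:
    """Per-gene signal intensity as the row-vector norm."""
    if norm == "l2":
        return np.linalg.norm(expr.values, axis=1)
    if norm == "l1":
        return np.abs(expr.values).sum(axis=1)
    raise ValueError("norm must be 'l1' or 'l2'")


def filter_genes(expr: ExpressionMatrix, low_q: float = 0.05,
                 high_q: float = 0.95, norm: str = "l2") -> ExpressionMatrix:
    """Drop genes whose intensity falls outside [low_q, high_q] quantiles.

    Quantiles are taken over the distribution of per-gene norms; genes with
    norm strictly below the low quantile or strictly above the high
    quantile are removed, preserving the input gene order.
    """
    if not 0.0 <= low_q < high_q <= 1.0:
        raise ValueError("need 0 <= low_q < high_q <= 1")
    norms = gene_norms(expr, norm)
    lo, hi = np.quantile(norms, [low_q, high_q])
    keep = (norms >= lo) & (norms <= hi)
    if not keep.any():
        raise ValueError("empty matrix after filtering")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_genes: removed %d/%d genes outside [%g, %g] "
                    "intensity quantiles", n_drop, expr.n_genes, low_q, high_q)
    return expr.subset_genes(keep)


def sum_normalize(expr: ExpressionMatrix) -> GeneVectorSet:
    """Divide each gene row by its sum, dropping all-zero genes."""
    sums = expr.values.sum(axis=1)
    zero = sums <= 0
    if zero.any():
        dropped = [expr.gene_ids[i] for i in np.flatnonzero(zero)]
        logger.info("sum_normalize: dropped %d all-zero genes (e.g. %s)",
                    len(dropped), dropped[:3])
        expr = expr.subset_genes(~zero)
        sums = sums[~zero]
    vectors = expr.values / sums[:, None]
    return GeneVectorSet(list(expr.gene_ids), vectors, raw_ref=expr)


def reduce_samples(expr: ExpressionMatrix, mode: str = "none",
                   target_dim: int | None = None) -> ExpressionMatrix:
    """Optionally reduce the number of sample columns.

    ``sample_cluster`` groups samples by complete-linkage clustering of
    their expression columns and replaces each group by its column mean —
    the natural choice for replicate designs, and it preserves
    non-negativity.  ``pca`` projects onto the top components and clamps
    negatives to zero (with a warning), which breaks the convex geometry
    less gracefully and is therefore not the default.
    """
    if mode == "none":
        return expr
    if target_dim is None:
        raise ValueError("target_dim required for reduction")
    if not 2 <= target_dim <= expr.n_samples:
        raise ValueError(
            f"target_dim must be in [2, {expr.n_samples}], got {target_dim}"
        )
    if mode == "sample_cluster":
        from sklearn.cluster import AgglomerativeClustering

        labels = AgglomerativeClustering(
            n_clusters=target_dim, linkage="complete"
        ).fit_predict(expr.values.T)
        # order clusters by first occurrence to keep sample order stable
        order, seen = [], set()
        for lab in labels:
            if lab not in seen:
                seen.add(lab)
                order.append(lab)
        cols, names = [], []
        for lab in order:
            members = np.flatnonzero(labels == lab)
            cols.append(expr.values[:, members].mean(axis=1))
            names.append("+".join(expr.sample_ids[m] for m in members))
        return ExpressionMatrix(list(expr.gene_ids), names, np.column_stack(cols))
    if mode == "pca":
        from sklearn.decomposition import PCA

        scores = PCA(n_components=target_dim, random_state=0).fit_transform(expr.values)
        n_neg = int((scores < 0).sum())
        if n_neg:
            logger.warning("reduce_samples(pca): clamped %d negative scores to 0 "
                           "(PCA does not preserve non-negativity)", n_neg)
        scores = np.clip(scores, 0.0, None)
        names = [f"PC{i + 1}" for i in range(target_dim)]
        return ExpressionMatrix(list(expr.gene_ids), names, scores)
    raise ValueError(f"unknown reduction mode {mode!r}")
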