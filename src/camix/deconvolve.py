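"""Proportion estimation from marker genes and NNLS profile recovery.

Once marker genes are known, each subpopulation's mixing-proportion
column is the standardized average of its markers' raw expression
vectors: markers are expressed in a single subpopulation, so their
normalized expression across samples is (up to noise) exactly the
normalized mixing column.  Per-column scales are then fixed by the
constraint that every sample's proportions sum to one.  Given the
proportions, subpopulation-specific expression profiles are recovered
gene-by-gene with non-negative least squares on the raw (linear-scale)
matrix, so profiles keep interpretable intensity units.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.optimize import nnls

from .io import ExpressionMatrix

logger = logging.getLogger("camix")


@dataclasses.dataclass
class DeconvolutionResult:
    A_hat: np.ndarray             # (J, K) proportions, rows sum to 1
    S_hat: np.ndarray             # (N, K) non-negative profiles
    per_gene_residual: np.ndarray  # (N,) NNLS residual norms


def standardized_marker_average(expr: ExpressionMatrix, marker_sets: dict,
                                norm_choice: str = "l1") -> np.ndarray:
    """Per-subpopulation mean of norm-standardized marker expression vectors.

    Returns a J x K matrix whose k-th column is
    (1/n_k) * sum_{i in MG-k} x(i) / ||x(i)||.
    """
    if norm_choice not in ("l1", "l2"):
        raise ValueError("norm_choice must be 'l1' or 'l2'")
    ord_ = 1 if norm_choice == "l1" else 2
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    keys = sorted(marker_sets)
    cols = []
    for k in keys:
        markers = marker_sets[k]
        if not markers:
            raise ValueError(f"empty marker set for subpopulation {k!r}")
        missing = [g for g in markers if g not in gene_pos]
        if missing:
            raise ValueError(
                f"markers absent from expression matrix for subpopulation "
                f"{k!r}: {sorted(missing)[:5]}"
            )
        rows = expr.values[[gene_pos[g] for g in sorted(markers)]]
        norms = np.linalg.norm(rows, ord=ord_, axis=1)
        if np.any(norms <= 0):
            raise ValueError(f"all-zero marker gene in subpopulation {k!r}")
        cols.append((rows / norms[:, None]).mean(axis=0))
    return np.column_stack(cols)


def estimate_proportions(expr: ExpressionMatrix, marker_sets: dict,
                         norm_choice: str = "l1") -> np.ndarray:
    """Estimate the J x K mixing matrix from marker-gene expression.

    Standardized averaging gives each mixing column up to a positive
    scale; scales are recovered from C @ lam = 1 (unit row sums) and the
    rows renormalized to absorb residual noise.
    """
    C = standardized_marker_average(expr, marker_sets, norm_choice)
    lam, _ = nnls(C, np.ones(C.shape[0]))
    if np.any(lam <= 0):
        lam = np.clip(
            np.linalg.lstsq(C, np.ones(C.shape[0]), rcond=None)[0], 1e-12, None
        )
    A = C * lam[None, :]
    rows = A.sum(axis=1, keepdims=True)
    if np.any(rows <= 0):
        raise ValueError("degenerate marker averages: zero proportion row")
    return A / rows


def estimate_profiles(expr: ExpressionMatrix, A_hat: np.ndarray):
    """Per-gene NNLS recovery of subpopulation profiles.

    Solves S_hat[i] = argmin_{s >= 0} || x_raw(i) - A_hat s ||_2 for every
    gene independently on the raw expression scale.  Requires J >= K
    (with J < K the per-gene systems are underdetermined and profiles are
    not identifiable) and a full-column-rank A_hat.
    """
    A_hat = np.asarray(A_hat, dtype=float)
    J, K = A_hat.shape
    if expr.n_samples != J:
        raise ValueError(f"A_hat has {J} rows but matrix has {expr.n_samples} samples")
    if J < K:
        raise ValueError(
            f"underdetermined deconvolution: {J} samples < {K} subpopulations; "
            "subpopulation-specific profiles cannot be estimated"
        )
    if np.linalg.matrix_rank(A_hat, tol=1e-10) < K:
        raise ValueError("A_hat is rank-deficient; profiles are not identifiable")
    N = expr.n_genes
    S_hat = np.zeros((N, K))
    resid = np.zeros(N)
    for i in range(N):
        x = expr.values[i]
        if not x.any():
            continue  # all-zero gene: zero profile, zero residual
        S_hat[i], resid[i] = nnls(A_hat, x)
    return S_hat, resid


def deconvolve(expr: ExpressionMatrix, marker_sets: dict,
               norm_choice: str = "l1") -> DeconvolutionResult:
    """Full deconvolution: proportions from markers, then NNLS profiles."""
    A_hat = estimate_proportions(expr, marker_sets, norm_choice)
    S_hat, resid = estimate_profiles(expr, A_hat)
    logger.info("deconvolve: K=%d, median per-gene residual %.4g",
                A_hat.shape[1], float(np.median(resid)))
    return DeconvolutionResult(A_hat=A_hat, S_hat=S_hat, per_gene_residual=resid)
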