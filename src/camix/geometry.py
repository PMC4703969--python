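"""Scatter-simplex geometry: margins, vertex search, marker assignment.

In the sum-standardized scatter space each gene is a point on the unit
simplex in sample space.  Under the linear mixing model the cloud of gene
points is contained in the convex hull of the (normalized) mixing-matrix
columns, and genes expressed in exactly one subpopulation sit at the hull
vertices.  The vertex search therefore asks: which K of the M cluster
centers form the convex hull that most tightly encloses the remaining
M - K "exterior" centers?  Tightness is the sum of margins-of-error —
Euclidean distances from each exterior center to the candidate hull — and
the minimizing subset is found by exhaustive enumeration of all C(M, K)
subsets (compiled kernel in :mod:`camix._kernels`).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from itertools import combinations

import numpy as np
from scipy.optimize import nnls

from . import _kernels
from .clustering import ClusterSet

logger = logging.getLogger("camix")


class DegenerateSimplexError(ValueError):
    """No full-rank K-vertex model exists for these cluster centers.

    Raised when every candidate subset is numerically rank-deficient or
    the winning subset yields linearly dependent mixing columns — e.g.
    when K exceeds the affine dimension of noise-free data."""


@dataclasses.dataclass
class SimplexModel:
    """A fitted K-vertex simplex over cluster centers."""

    K: int
    vertex_cluster_indices: tuple      # K distinct cluster indices, sorted
    A: np.ndarray                      # (J, K) mixing matrix, rows sum to 1
    marker_sets: dict                  # subpopulation index -> set of gene ids
    fit_error: float                   # total exterior margin-of-error

    def __post_init__(self):
        if np.any(self.A < -1e-12):
            raise ValueError("mixing matrix must be non-negative")
        # scale-invariant independence check (columns may carry very
        # different proportions when K exceeds the true source count)
        norms = np.linalg.norm(self.A, axis=0)
        if np.any(norms <= 0):
            raise ValueError("mixing matrix has a zero column")
        if np.linalg.matrix_rank(self.A / norms, tol=1e-8) < self.K:
            raise ValueError("mixing matrix columns must be linearly independent")


def project_to_hull(g: np.ndarray, vertices: np.ndarray):
    """Euclidean projection of g onto the convex hull of vertex columns.

    Solves min ||g - V alpha|| s.t. alpha >= 0, sum(alpha) = 1 exactly, by
    enumerating supports of the simplex-constrained least-squares problem.
    Returns (distance, alpha).
    """
    V = np.asarray(vertices, dtype=float)
    g = np.asarray(g, dtype=float)
    J, K = V.shape
    if g.shape != (J,):
        raise ValueError(f"dimension mismatch: point has {g.shape[0]} "
                         f"coordinates, vertices have {J}")
    best_d2 = np.inf
    best_alpha = None
    for r in range(1, K + 1):
        for sub in combinations(range(K), r):
            Vs = V[:, sub]
            Gs = Vs.T @ Vs
            kkt = np.zeros((r + 1, r + 1))
            kkt[:r, :r] = Gs
            kkt[:r, r] = 1.0
            kkt[r, :r] = 1.0
            rhs = np.append(Vs.T @ g, 1.0)
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:
                continue
            a = sol[:r]
            if np.any(a < -1e-10):
                continue
            d2 = float(np.sum((Vs @ a - g) ** 2))
            if d2 < 3e-17 * (1.0 + float(g @ g)):
                d2 = 0.0
            if d2 < best_d2:
                best_d2 = d2
                best_alpha = np.zeros(K)
                best_alpha[list(sub)] = a
    if best_alpha is None:  # all supports singular: fall back to vertex distances
        d2s = np.sum((V - g[:, None]) ** 2, axis=0)
        k = int(np.argmin(d2s))
        best_d2 = float(d2s[k])
        best_alpha = np.zeros(K)
        best_alpha[k] = 1.0
    return math.sqrt(max(best_d2, 0.0)), best_alpha


def margin_of_error(g, vertices) -> float:
    """Distance from a simplex point to the convex hull of given vertices.

    Zero (up to 1e-9) when g lies inside the hull.  All vectors must be
    sum-standardized (unit sum).
    """
    V = np.atleast_2d(np.asarray(vertices, dtype=float))
    if V.shape[0] >= 1 and V.ndim == 2 and V.shape[1] != np.asarray(g).shape[0]:
        raise ValueError("dimension mismatch between point and vertices")
    d, _ = project_to_hull(np.asarray(g, float), V.T)
    return d


def rescale_to_mixing(centers_k: np.ndarray) -> np.ndarray:
    """Turn K unit-sum vertex centers into a J x K mixing matrix.

    The scatter-simplex vertices are the mixing columns up to positive
    per-column scales; the scales are recovered from the constraint that
    each sample's proportions sum to one, i.e. C @ lam = 1 with lam >= 0,
    then rows are normalized to remove any residual.
    """
    C = np.asarray(centers_k, dtype=float).T  # (J, K)
    lam, _ = nnls(C, np.ones(C.shape[0]))
    if np.any(lam <= 0):
        # fall back to unconstrained least squares clipped away from zero
        lam = np.abs(np.linalg.lstsq(C, np.ones(C.shape[0]), rcond=None)[0])
    if lam.max() <= 0:
        raise ValueError("degenerate vertex set: no positive column scaling")
    lam = np.maximum(lam, 1e-9 * lam.max())  # keep every vertex represented
    A = C * lam[None, :]
    A = np.clip(A, 0.0, None)
    rows = A.sum(axis=1, keepdims=True)
    if np.any(rows <= 0):
        raise ValueError("degenerate vertex set: zero sample row in mixing matrix")
    return A / rows


def find_vertices(clusters: ClusterSet, K: int,
                  subset_budget: float = 5e6) -> SimplexModel:
    """Exhaustively locate the K cluster centers forming the scatter simplex.

    Enumerates all C(M, K) vertex subsets, scoring each by the summed
    margin-of-error of the exterior centers, and returns the minimizer
    (lexicographically smallest index set on ties within 1e-12).
    Candidates whose center matrix is numerically rank-deficient are
    skipped.  A farthest-point greedy subset primes the branch-and-bound
    cutoff; exterior centers are visited most-extreme-first so that poor
    candidates are rejected after a few margin evaluations.
    """
    M = clusters.n_clusters
    if not 1 <= K <= M:
        raise ValueError(f"K must be in [1, {M}], got {K}")
    n_subsets = math.comb(M, K)
    if n_subsets > subset_budget:
        raise ValueError(
            f"C({M},{K}) = {n_subsets} candidate subsets exceeds the budget "
            f"({subset_budget:g}); lower the number of clusters M or K, or "
            "raise subset_budget"
        )
    C = np.ascontiguousarray(clusters.centers)
    G = C @ C.T
    diag = np.diag(G)
    d2c = diag - 2.0 * G.mean(axis=1) + G.mean()
    order = np.argsort(-d2c).astype(np.int64)

    # farthest-point greedy warm start (prunes, never decides)
    sel = [int(np.argmax(d2c))]
    while len(sel) < K:
        dmin = np.min(diag[:, None] - 2.0 * G[:, sel] + diag[sel][None, :], axis=1)
        dmin[sel] = -np.inf
        nxt = int(np.argmax(dmin))
        sel.append(nxt)
    init = np.sort(np.array(sel, dtype=np.int64))

    best_c, best_sum, n_eval = _kernels.exhaustive_search(
        G, C, K, order, init, float(n_subsets) + 1
    )
    if best_sum >= 1e300:
        raise DegenerateSimplexError(
            f"no full-rank candidate subset of size K={K} found"
        )
    idx = tuple(int(i) for i in np.sort(best_c))
    try:
        A = rescale_to_mixing(C[list(idx)])
        model = SimplexModel(
            K=K,
            vertex_cluster_indices=idx,
            A=A,
            marker_sets={},
            fit_error=float(best_sum),
        )
    except ValueError as exc:
        raise DegenerateSimplexError(
            f"K={K} vertex model is degenerate: {exc}"
        ) from exc
    model.marker_sets = identify_markers(model, clusters)
    logger.info("find_vertices: K=%d, vertices=%s, fit_error=%.6g "
                "(%d subsets evaluated)", K, idx, best_sum, abs(int(n_eval)))
    return model


def identify_markers(model: SimplexModel, clusters: ClusterSet) -> dict:
    """Marker genes of subpopulation k = members of the k-th vertex cluster."""
    marker_sets = {}
    for k, cluster_idx in enumerate(model.vertex_cluster_indices):
        marker_sets[k] = set(clusters.members(cluster_idx))
    return marker_sets


def cluster_margins(clusters: ClusterSet, model: SimplexModel) -> np.ndarray:
    """Margin-of-error of every cluster center w.r.t. the model's vertices."""
    C = np.ascontiguousarray(clusters.centers)
    G = C @ C.T
    c = np.asarray(model.vertex_cluster_indices, dtype=np.int64)
    return _kernels.margins_to_subset(G, C, c, len(c))
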