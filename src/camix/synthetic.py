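"""Ground-truthed synthetic mixtures for validating the pipeline.

The generator emulates the validation designs the method is aimed at:
non-negative pure profiles with planted exclusive marker genes, a
full-rank non-negative mixing matrix whose scatter-simplex geometry is
controlled by the minimal pairwise angle between mixing columns
("rotation"; smaller angles = a more compressed, harder simplex), and
additive truncated-Gaussian noise on the linear scale.

Mixing-matrix construction: columns are built as u_k = alpha * m + h_k,
where the h_k are disjoint-support unit block vectors (one block of
J // K samples per subpopulation) and m is their normalized mean.  All
column pairs then share the same angle, which shrinks monotonically as
alpha grows, so any requested minimal pairwise angle is reached by a
1-D root find; with equal blocks the row sums are constant, so a single
rescaling puts every sample row exactly on the unit simplex.  Sample
rows within a block are identical — mirroring replicated mixture
designs.  When K does not divide J, leftover samples get uniform
proportions (which bounds the achievable angle below 90 degrees).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.optimize import brentq

from .io import ExpressionMatrix

# Co-expressed (simplex-interior) genes are kept below 2/3 dominance: by
# the one-versus-everyone gold-standard rule at fold change 2, a gene
# drawing more than fc/(fc+1) = 2/3 of its expression from a single
# subpopulation is itself a marker, which the generator must not plant
# unlabelled.  Genes dominated by one subpopulation belong to the
# single-subpopulation class (coexpression_fraction < 1) instead.
MAX_COEXPRESSION_WEIGHT = 2.0 / 3.0


@dataclasses.dataclass
class MixtureGroundTruth:
    """Everything needed to score a deconvolution of a synthetic mixture."""

    S_true: np.ndarray        # (N, K) pure profiles
    A_true: np.ndarray        # (J, K) mixing matrix, rows sum to 1
    marker_truth: dict        # subpopulation -> set of gene ids
    noise_sd: float
    seed: int
    gene_ids: list
    sample_ids: list

    def __post_init__(self):
        gene_pos = {g: i for i, g in enumerate(self.gene_ids)}
        for k, genes in self.marker_truth.items():
            idx = [gene_pos[g] for g in genes]
            sub = self.S_true[idx]
            if not np.all(sub[:, k] > 0):
                raise ValueError(f"marker genes of subpopulation {k} must be expressed")
            other = np.delete(sub, k, axis=1)
            if np.any(other != 0):
                raise ValueError(
                    f"marker genes of subpopulation {k} must be silent elsewhere"
                )
        if np.linalg.matrix_rank(self.A_true) < self.A_true.shape[1]:
            raise ValueError("mixing matrix must have full column rank")


def generate_profiles(n_genes: int, K: int, n_markers_per_k: int,
                      coexpression_fraction: float = 1.0, seed: int = 0,
                      log_mean: float = 5.0, log_sigma: float = 1.0):
    """Pure profiles with planted exclusive markers.

    Marker genes get a log-normal expression level in exactly one
    subpopulation and zero elsewhere.  A ``coexpression_fraction`` of the
    remaining genes are simplex-interior: random non-negative combinations
    of >= 2 subpopulations with no weight above
    ``MAX_COEXPRESSION_WEIGHT``.  The rest are expressed in a single
    random subpopulation (unplanted, marker-like genes).

    Returns (S_true, marker_truth, gene_ids).
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if n_genes < K * n_markers_per_k:
        raise ValueError(
            f"{n_genes} genes cannot hold {K}x{n_markers_per_k} markers"
        )
    if not 0.0 <= coexpression_fraction <= 1.0:
        raise ValueError("coexpression_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    magnitudes = rng.lognormal(mean=log_mean, sigma=log_sigma, size=n_genes)
    S = np.zeros((n_genes, K))

    perm = rng.permutation(n_genes)
    marker_idx = perm[: K * n_markers_per_k]
    rest = perm[K * n_markers_per_k:]
    marker_truth = {}
    for k in range(K):
        idx = marker_idx[k * n_markers_per_k:(k + 1) * n_markers_per_k]
        S[idx, k] = magnitudes[idx]
        marker_truth[k] = {gene_ids[i] for i in idx}

    n_co = int(round(coexpression_fraction * rest.size))
    co, single = rest[:n_co], rest[n_co:]
    for i in co:
        t = int(rng.integers(2, K + 1))
        subs = rng.choice(K, size=t, replace=False)
        while True:
            w = rng.dirichlet(np.ones(t))
            if w.max() <= MAX_COEXPRESSION_WEIGHT:
                break
        S[i, subs] = magnitudes[i] * w
    if single.size:
        S[single, rng.integers(0, K, size=single.size)] = magnitudes[single]
    return S, marker_truth, gene_ids


def _block_mixing(J: int, K: int, alpha: float) -> np.ndarray:
    """Equiangular column construction; rows normalized to unit sum."""
    b = J // K
    r = J - K * b
    h = np.zeros((K * b, K))
    for k in range(K):
        h[k * b:(k + 1) * b, k] = 1.0 / math.sqrt(b)
    m = h.sum(axis=1) / math.sqrt(K)
    U = alpha * m[:, None] + h
    if r:
        U = np.vstack([U, np.full((r, K), 1.0 / K)])
    return U / U.sum(axis=1, keepdims=True)


def min_pairwise_angle(A: np.ndarray) -> float:
    """Minimal pairwise angle (degrees) between the columns of A."""
    C = A / np.linalg.norm(A, axis=0, keepdims=True)
    G = np.clip(C.T @ C, -1.0, 1.0)
    K = A.shape[1]
    iu = np.triu_indices(K, k=1)
    return float(np.degrees(np.arccos(G[iu].max())))


def generate_mixing(J: int, K: int, rotation_deg: float,
                    seed: int = 0) -> np.ndarray:
    """Non-negative mixing matrix with a requested minimal column angle.

    Rows lie on the unit simplex; the minimal pairwise angle between
    column directions equals ``rotation_deg`` (within 0.5 degrees).  The
    sample rows are randomly permuted with the given seed.
    """
    if J < K or K < 2:
        raise ValueError(f"need J >= K >= 2, got J={J}, K={K}")
    if not 0.0 < rotation_deg <= 90.0:
        raise ValueError("rotation_deg must be in (0, 90]")

    max_angle = min_pairwise_angle(_block_mixing(J, K, 0.0))
    if rotation_deg > max_angle + 0.5:
        raise ValueError(
            f"angle {rotation_deg} deg unachievable for J={J}, K={K}: "
            f"maximum is {max_angle:.2f} deg"
        )

    if rotation_deg >= max_angle:
        alpha = 0.0
    else:
        hi = 1.0
        while min_pairwise_angle(_block_mixing(J, K, hi)) > rotation_deg:
            hi *= 2.0
            if hi > 1e6:
                raise ValueError("failed to bracket the rotation angle")
        alpha = brentq(
            lambda a: min_pairwise_angle(_block_mixing(J, K, a)) - rotation_deg,
            0.0, hi, xtol=1e-12,
        )
    A = _block_mixing(J, K, alpha)
    achieved = min_pairwise_angle(A)
    if abs(achieved - rotation_deg) > 0.5 and rotation_deg <= max_angle:
        raise ValueError(
            f"constructed angle {achieved:.3f} deg misses target {rotation_deg}"
        )
    if np.linalg.matrix_rank(A) < K:  # equiangular frame is full rank by design
        raise ValueError("constructed mixing matrix is rank-deficient")
    rng = np.random.default_rng(seed)
    return A[rng.permutation(J)]


def mix(S_true: np.ndarray, A_true: np.ndarray, noise_sd: float = 0.0,
        seed: int = 0, gene_ids=None, sample_ids=None) -> ExpressionMatrix:
    """Mixture matrix X = S A^T plus truncated additive Gaussian noise.

    The noise standard deviation is ``noise_sd`` times the mean of the
    noise-free mixture; negative values are clamped to zero.
    """
    S = np.asarray(S_true, dtype=float)
    A = np.asarray(A_true, dtype=float)
    if S.shape[1] != A.shape[1]:
        raise ValueError("S and A disagree on the number of subpopulations")
    X = S @ A.T
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        X = X + rng.normal(0.0, noise_sd * X.mean(), size=X.shape)
        np.clip(X, 0.0, None, out=X)
    if gene_ids is None:
        gene_ids = [f"g{i:05d}" for i in range(S.shape[0])]
    if sample_ids is None:
        sample_ids = [f"s{j:02d}" for j in range(A.shape[0])]
    return ExpressionMatrix(list(gene_ids), list(sample_ids), X)


def simulate_mixture(n_genes: int = 2000, K: int = 3, J: int = 9,
                     n_markers_per_k: int = 30, rotation_deg: float = 45.0,
                     noise_sd: float = 0.01, coexpression_fraction: float = 1.0,
                     seed: int = 0):
    """One synthetic validation panel; returns (ExpressionMatrix, truth).

    Defaults mirror the reference validation design: K = 3 subpopulations,
    J = 9 samples, 2000 genes, 30 planted markers per subpopulation,
    1% additive noise, selectable 30/45/60-degree simplex rotation.
    """
    ss = np.random.SeedSequence(seed)
    s_prof, s_mix, s_noise = (int(c.generate_state(1)[0] % (2**31))
                              for c in ss.spawn(3))
    S, marker_truth, gene_ids = generate_profiles(
        n_genes, K, n_markers_per_k, coexpression_fraction, seed=s_prof
    )
    A = generate_mixing(J, K, rotation_deg, seed=s_mix)
    expr = mix(S, A, noise_sd, seed=s_noise, gene_ids=gene_ids)
    truth = MixtureGroundTruth(
        S_true=S, A_true=A, marker_truth=marker_truth, noise_sd=noise_sd,
        seed=seed, gene_ids=gene_ids, sample_ids=list(expr.sample_ids),
    )
    return expr, truth
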