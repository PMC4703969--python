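"""Scoring of deconvolution output against ground truth.

The output of an unsupervised deconvolution is only defined up to a
permutation (and, for the mixing matrix, positive column scaling) of the
subpopulation labels, so every criterion here either is invariant to
those transformations (the E1 cross-talk index) or aligns labels first
by maximum-overlap / maximum-correlation Hungarian matching (Pearson
correlations, marker confusion).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr

from .deconvolve import estimate_profiles
from .io import ExpressionMatrix


@dataclasses.dataclass
class EvaluationReport:
    e1: float
    pearson_proportions: float
    pearson_profiles_markers: list      # per-subpopulation r over marker genes
    pearson_profiles_all: list          # per-subpopulation r over all genes
    marker_sensitivity: float
    marker_specificity: float
    venn_counts: tuple                  # (both, cam_only, truth_only)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def compute_e1(A_hat: np.ndarray, A_true: np.ndarray) -> float:
    """Permutation/scale-invariant cross-talk index of a mixing estimate.

    With P = pinv(A_hat) @ A_true, sums over rows and columns how far P is
    from a positively scaled permutation matrix; 0 iff the estimate equals
    the truth up to column permutation and positive scaling.
    """
    A_hat = np.asarray(A_hat, dtype=float)
    A_true = np.asarray(A_true, dtype=float)
    if A_hat.shape != A_true.shape:
        raise ValueError("mixing matrices must have identical shapes")
    K = A_hat.shape[1]
    if np.linalg.matrix_rank(A_hat, tol=1e-10) < K:
        raise ValueError("A_hat is rank-deficient; E1 undefined")
    P = np.abs(np.linalg.pinv(A_hat) @ A_true)
    row = (P.sum(axis=1) / P.max(axis=1) - 1.0).sum()
    col = (P.sum(axis=0) / P.max(axis=0) - 1.0).sum()
    return float(row + col)


def align_columns(A_hat: np.ndarray, A_true: np.ndarray) -> np.ndarray:
    """Column indices p of A_hat maximizing correlation: A_hat[:, p] ~ A_true.

    Handles K_hat != K_true (e.g. model selection over- or under-shot):
    each truth column is matched to a distinct estimated column; the
    returned index array has min(K_hat, K_true) entries, ordered by
    truth column.
    """
    Kh, Kt = A_hat.shape[1], A_true.shape[1]
    cost = np.zeros((Kt, Kh))
    for j in range(Kt):
        for i in range(Kh):
            sd = A_hat[:, i].std() * A_true[:, j].std()
            if sd > 0:
                cost[j, i] = -np.corrcoef(A_true[:, j], A_hat[:, i])[0, 1]
            else:
                cost[j, i] = np.sum((A_hat[:, i] - A_true[:, j]) ** 2)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(len(rows), dtype=int)
    perm[rows] = cols
    return perm


def align_marker_sets(predicted: dict, truth: dict) -> dict:
    """Map each truth label to the predicted label of maximal overlap."""
    p_keys = sorted(predicted)
    t_keys = sorted(truth)
    overlap = np.zeros((len(t_keys), len(p_keys)))
    for a, tk in enumerate(t_keys):
        for b, pk in enumerate(p_keys):
            overlap[a, b] = len(truth[tk] & predicted[pk])
    rows, cols = linear_sum_assignment(-overlap)
    return {t_keys[a]: p_keys[b] for a, b in zip(rows, cols)}


def marker_confusion(predicted: dict, truth: dict, universe: set):
    """Pooled sensitivity/specificity of marker detection.

    Labels are aligned by maximum-overlap matching.  Sensitivity counts a
    truth marker as recovered only when it is predicted for the aligned
    subpopulation; specificity is the fraction of non-marker genes (by
    truth) that are not called markers at all.  Also returns Venn counts
    (both, predicted-only, truth-only) on the aligned pooled sets.
    """
    if not truth or all(len(v) == 0 for v in truth.values()):
        raise ValueError("empty truth marker sets")
    t_union = set().union(*truth.values())
    p_union = set().union(*predicted.values()) if predicted else set()
    if not (t_union <= universe and p_union <= universe):
        raise ValueError("marker sets must be subsets of the gene universe")
    mapping = align_marker_sets(predicted, truth) if predicted else {}
    tp = sum(len(truth[tk] & predicted[pk]) for tk, pk in mapping.items())
    sensitivity = tp / len(t_union)
    negatives = universe - t_union
    fp = len(p_union & negatives)
    specificity = (len(negatives) - fp) / len(negatives) if negatives else 1.0
    venn = (tp, len(p_union) - tp, len(t_union) - tp)
    return sensitivity, specificity, venn


def fold_change_markers(pure_profiles: np.ndarray, fc_threshold: float = 2.0,
                        gene_ids=None) -> dict:
    """One-versus-everyone gold-standard markers from pure profiles.

    Gene i is a marker of subpopulation k iff its pure expression there is
    positive and at least ``fc_threshold`` times the maximum across all
    other subpopulations.
    """
    S = np.asarray(pure_profiles, dtype=float)
    if fc_threshold <= 1.0:
        raise ValueError("fc_threshold must be > 1")
    N, K = S.shape
    if K < 2:
        raise ValueError("need at least 2 subpopulations")
    if gene_ids is None:
        gene_ids = list(range(N))
    out = {k: set() for k in range(K)}
    for k in range(K):
        others = np.delete(S, k, axis=1).max(axis=1)
        hit = (S[:, k] > 0) & (S[:, k] >= fc_threshold * others)
        out[k] = {gene_ids[i] for i in np.flatnonzero(hit)}
    return out


def supervised_profiles_baseline(expr: ExpressionMatrix, A_known: np.ndarray):
    """Profile recovery with externally supplied (reference) proportions.

    The supervised counterpart of the blind pipeline: identical NNLS
    per-gene regression, but the mixing matrix comes from prior knowledge
    instead of detected markers.
    """
    return estimate_profiles(expr, A_known)


def perturb_proportions(A: np.ndarray, magnitude: float, seed: int = 0) -> np.ndarray:
    """Additive uniform perturbation of proportions, re-projected to the simplex."""
    if not 0.0 <= magnitude <= 0.5:
        raise ValueError("magnitude must be in [0, 0.5]")
    A = np.asarray(A, dtype=float)
    if magnitude == 0.0:
        return A.copy()
    rng = np.random.default_rng(seed)
    out = A + rng.uniform(-magnitude, magnitude, size=A.shape)
    np.clip(out, 0.0, None, out=out)
    rows = out.sum(axis=1, keepdims=True)
    rows[rows == 0] = 1.0
    return out / rows


def perturb_signatures(S: np.ndarray, pct: float, seed: int = 0) -> np.ndarray:
    """Multiplicative +-pct perturbation of reference signatures."""
    if not 0.0 <= pct <= 1.0:
        raise ValueError("pct must be in [0, 1]")
    S = np.asarray(S, dtype=float)
    if pct == 0.0:
        return S.copy()
    rng = np.random.default_rng(seed)
    out = S * (1.0 + rng.uniform(-pct, pct, size=S.shape))
    return np.clip(out, 0.0, None)


def profile_correlations(S_hat: np.ndarray, S_true: np.ndarray,
                         marker_idx_per_k: dict):
    """Per-subpopulation Pearson r of profiles, over markers and all genes.

    Columns of S_hat are assumed already aligned to S_true.  Correlation
    over all genes is inflated by co-expressed genes; the marker-restricted
    correlation is the informative one and both are reported.
    """
    K = S_true.shape[1]
    r_mark, r_all = [], []
    for k in range(K):
        if k >= S_hat.shape[1]:  # truth column with no matched estimate
            r_mark.append(np.nan)
            r_all.append(np.nan)
            continue
        idx = sorted(marker_idx_per_k.get(k, []))
        r_all.append(_safe_pearson(S_hat[:, k], S_true[:, k]))
        if len(idx) >= 2:
            r_mark.append(_safe_pearson(S_hat[idx, k], S_true[idx, k]))
        else:
            r_mark.append(np.nan)
    return r_mark, r_all


def _safe_pearson(x, y):
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(pearsonr(x, y)[0])


def evaluate_deconvolution(A_hat: np.ndarray, A_true: np.ndarray,
                           S_hat: np.ndarray, S_true: np.ndarray,
                           predicted_markers: dict, truth_markers: dict,
                           gene_ids) -> EvaluationReport:
    """Full scorecard for one synthetic-mixture deconvolution.

    When the estimated and true subpopulation counts differ, columns are
    matched by maximum correlation and scores are computed over the
    matched columns; the E1 index is undefined (NaN) in that case.
    """
    perm = align_columns(A_hat, A_true)
    A_al = A_hat[:, perm]
    S_al = S_hat[:, perm]
    same_k = A_hat.shape[1] == A_true.shape[1]
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    # truth marker sets may be keyed by arbitrary labels; map them to
    # profile column positions by sorted label order
    marker_idx = {
        pos: [gene_pos[g] for g in truth_markers[key] if g in gene_pos]
        for pos, key in enumerate(sorted(truth_markers))
    }
    r_mark, r_all = profile_correlations(S_al, S_true, marker_idx)
    sens, spec, venn = marker_confusion(predicted_markers, truth_markers,
                                        set(gene_ids))
    return EvaluationReport(
        e1=compute_e1(A_hat, A_true) if same_k else float("nan"),
        pearson_proportions=_safe_pearson(A_al.ravel(), A_true.ravel()),
        pearson_profiles_markers=r_mark,
        pearson_profiles_all=r_all,
        marker_sensitivity=sens,
        marker_specificity=spec,
        venn_counts=venn,
    )
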