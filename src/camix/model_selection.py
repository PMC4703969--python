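"""MDL-based choice of the number of subpopulations K.

Each candidate K is scored by a two-part description length over the M
cluster centers: an isotropic-Gaussian negative log-likelihood of the
center residuals around their projections onto the fitted K-vertex
simplex, plus parameter-coding penalties for the mixing matrix
((K-1) * J * log(M) / 2) and the subpopulation profiles
(K * M * log(J) / 2).  The plug-in variance is the mean squared residual,
floored at a tiny epsilon so that exact (noise-free) fits stay finite;
natural logarithms are used throughout, which leaves the argmin unchanged.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd

from .clustering import ClusterSet
from .geometry import DegenerateSimplexError, SimplexModel, cluster_margins, find_vertices

logger = logging.getLogger("camix")

RSS_FLOOR = 1e-12


@dataclasses.dataclass
class MDLEntry:
    K: int
    neg_log_likelihood: float
    penalty: float
    total: float
    floored: bool = False  # True when the RSS hit the epsilon floor


@dataclasses.dataclass
class MDLCurve:
    """Description length per candidate K and the selected minimum."""

    entries: dict                     # K -> MDLEntry
    selected_K: int

    def to_frame(self) -> pd.DataFrame:
        rows = {
            k: {
                "neg_log_likelihood": e.neg_log_likelihood,
                "penalty": e.penalty,
                "total": e.total,
            }
            for k, e in sorted(self.entries.items())
        }
        return pd.DataFrame.from_dict(rows, orient="index")


def mdl_penalty(K: int, J: int, M: int) -> float:
    """Parameter-coding cost in nats: (K-1)J ln(M)/2 + K M ln(J)/2."""
    return (K - 1) * J * math.log(M) / 2.0 + K * M * math.log(J) / 2.0


def compute_mdl(clusters: ClusterSet, model: SimplexModel,
                eps: float = RSS_FLOOR) -> MDLEntry:
    """Description length of the cluster centers under a fitted simplex.

    ``eps`` floors the plug-in variance so exact (noise-free) fits keep a
    finite code length; hitting the floor is flagged, not an error.
    """
    M, J = clusters.centers.shape
    margins = cluster_margins(clusters, model)
    rss = float(np.sum(margins ** 2))
    floored = rss < eps
    sigma2 = max(rss / (M * J), eps)
    nll = (M * J / 2.0) * (math.log(2.0 * math.pi * sigma2) + 1.0)
    pen = mdl_penalty(model.K, J, M)
    return MDLEntry(model.K, nll, pen, nll + pen, floored)


def select_model(clusters: ClusterSet, k_range,
                 subset_budget: float = 5e6, eps: float = RSS_FLOOR):
    """Fit every K in k_range and pick the one minimizing total code length.

    Returns (MDLCurve, best SimplexModel); ties within 1e-12 go to the
    smaller K.
    """
    k_min, k_max = int(k_range[0]), int(k_range[-1])
    M, J = clusters.centers.shape
    upper = min(J, M)
    ks = [k for k in range(k_min, k_max + 1) if k <= upper]
    if not ks:
        raise ValueError(
            f"empty feasible K range: [{k_min}, {k_max}] with J={J}, M={M}"
        )
    entries = {}
    models = {}
    for K in ks:
        try:
            model = find_vertices(clusters, K, subset_budget=subset_budget)
        except DegenerateSimplexError as exc:
            # K exceeds the affine dimension the centers span (typical for
            # overfit K on noise-free data): not a representable model
            logger.info("MDL K=%d skipped: %s", K, exc)
            continue
        entry = compute_mdl(clusters, model, eps=eps)
        entries[K] = entry
        models[K] = model
        logger.info("MDL K=%d: nll=%.4f penalty=%.4f total=%.4f",
                    K, entry.neg_log_likelihood, entry.penalty, entry.total)
    if not entries:
        raise DegenerateSimplexError(
            f"no representable model in K range [{k_min}, {k_max}]"
        )
    fitted = sorted(entries)
    best_k = fitted[0]
    for K in fitted[1:]:
        if entries[K].total < entries[best_k].total - 1e-12:
            best_k = K
    curve = MDLCurve(entries=entries, selected_K=best_k)
    return curve, models[best_k]
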