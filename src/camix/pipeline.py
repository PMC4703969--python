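"""End-to-end unsupervised deconvolution pipeline.

Stages: gene filtering -> (optional) sample reduction -> sum
standardization -> affinity-propagation aggregation -> exhaustive vertex
search with MDL model selection -> marker assignment -> proportion
estimation from markers -> per-gene NNLS profile recovery.
"""

from __future__ import annotations

import logging
import time

import numpy as np
import pandas as pd

from .clustering import cluster_genes
from .deconvolve import estimate_profiles, estimate_proportions
from .geometry import find_vertices
from .io import ExpressionMatrix, RunConfig, RunResult
from .model_selection import MDLCurve, compute_mdl, select_model
from .preprocess import filter_genes, reduce_samples, sum_normalize

logger = logging.getLogger("camix")


def run_cam(expr: ExpressionMatrix, config: RunConfig | None = None) -> RunResult:
    """Run the full blind deconvolution on a linear-scale expression matrix."""
    config = config or RunConfig()
    t0 = time.perf_counter()

    work = expr
    if config.filter_low_q > 0 or config.filter_high_q < 1:
        work = filter_genes(work, config.filter_low_q, config.filter_high_q)
    if config.reduction != "none":
        work = reduce_samples(work, config.reduction, config.target_dim)
    vectors = sum_normalize(work)
    logger.info("stage=preprocess genes=%d samples=%d elapsed=%.2fs",
                vectors.n_genes, vectors.n_samples, time.perf_counter() - t0)

    t1 = time.perf_counter()
    n_clusters = min(config.n_clusters, vectors.n_genes)
    clusters = cluster_genes(
        vectors, target_M=n_clusters, damping=config.damping,
        max_iter=config.max_iter, stable_iter=config.stable_iter,
    )
    logger.info("stage=clustering M=%d elapsed=%.2fs",
                clusters.n_clusters, time.perf_counter() - t1)

    t2 = time.perf_counter()
    k_max = min(config.k_max, vectors.n_samples, clusters.n_clusters)
    if k_max < config.k_min:
        raise ValueError(
            f"k_min={config.k_min} infeasible: only {vectors.n_samples} samples "
            f"and {clusters.n_clusters} clusters available"
        )
    if config.k_min == k_max:
        model = find_vertices(clusters, config.k_min,
                              subset_budget=config.subset_budget)
        entry = compute_mdl(clusters, model, eps=config.noise_floor)
        curve = MDLCurve(entries={entry.K: entry}, selected_K=entry.K)
    else:
        curve, model = select_model(clusters, (config.k_min, k_max),
                                    subset_budget=config.subset_budget,
                                    eps=config.noise_floor)
    logger.info("stage=model_selection selected_K=%d fit_error=%.6g elapsed=%.2fs",
                curve.selected_K, model.fit_error, time.perf_counter() - t2)

    t3 = time.perf_counter()
    A_hat = estimate_proportions(work, model.marker_sets, config.norm_choice)
    S_hat, _ = estimate_profiles(work, A_hat)
    logger.info("stage=deconvolve K=%d elapsed=%.2fs",
                A_hat.shape[1], time.perf_counter() - t3)

    subpop_names = [f"subpop_{k + 1}" for k in range(model.K)]
    marker_rows = [
        {"gene": g, "subpopulation": subpop_names[k],
         "cluster_id": model.vertex_cluster_indices[k]}
        for k in sorted(model.marker_sets)
        for g in sorted(model.marker_sets[k])
    ]
    result = RunResult(
        selected_K=curve.selected_K,
        mdl_curve=curve.to_frame(),
        mixing_matrix=pd.DataFrame(A_hat, index=work.sample_ids,
                                   columns=subpop_names),
        marker_table=pd.DataFrame(
            marker_rows, columns=["gene", "subpopulation", "cluster_id"]
        ),
        profiles=pd.DataFrame(np.clip(S_hat, 0.0, None), index=work.gene_ids,
                              columns=subpop_names),
        config=config.to_dict(),
        fit_error=model.fit_error,
    )
    logger.info("pipeline done: K=%d, %d markers, total %.2fs",
                result.selected_K, len(result.marker_table),
                time.perf_counter() - t0)
    return result
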