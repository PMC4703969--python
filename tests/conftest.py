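"""Shared fixtures: small ground-truthed mixtures built at test time."""

import numpy as np
import pytest

from camix import ExpressionMatrix, RunConfig, simulate_mixture


@pytest.fixture(scope="session")
def tiny_noisefree():
    """Small noise-free 3-source mixture with planted markers."""
    expr, truth = simulate_mixture(
        n_genes=600, K=3, J=9, n_markers_per_k=20, rotation_deg=45.0,
        noise_sd=0.0, seed=1,
    )
    return expr, truth


@pytest.fixture(scope="session")
def small_noisefree_result(tiny_noisefree):
    """Pipeline output on the tiny noise-free mixture at the true K."""
    from camix import run_cam

    expr, truth = tiny_noisefree
    cfg = RunConfig(k_min=3, k_max=3, n_clusters=30,
                    filter_low_q=0.0, filter_high_q=1.0)
    return run_cam(expr, cfg), expr, truth


@pytest.fixture
def toy_matrix():
    return ExpressionMatrix(
        ["g1", "g2", "g3"], ["s1", "s2"],
        np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
    )


def hull_point(rng, vertices, interior=True):
    """Random point inside (or at a face of) the hull of vertex rows."""
    K = vertices.shape[0]
    w = rng.dirichlet(np.ones(K))
    if not interior:
        w[rng.integers(K)] = 0.0
        w = w / w.sum()
    return w @ vertices
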