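"""Margin-of-error, exhaustive vertex search, marker assignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from camix import find_vertices, identify_markers, margin_of_error
from camix.clustering import ClusterSet
from camix.geometry import project_to_hull, rescale_to_mixing
from camix.preprocess import sum_normalize


def _cluster_set(centers):
    centers = np.asarray(centers, dtype=float)
    centers = centers / centers.sum(axis=1, keepdims=True)
    M = centers.shape[0]
    return ClusterSet(
        centers=centers,
        exemplar_ids=[f"g{i}" for i in range(M)],
        membership=np.arange(M),
        sizes=np.ones(M, dtype=int),
        gene_ids=[f"g{i}" for i in range(M)],
    )


def test_margin_zero_at_vertex_and_inside_hull():
    v = np.array([[0.7, 0.2, 0.1], [0.1, 0.7, 0.2], [0.2, 0.1, 0.7]])
    assert margin_of_error(v[0], v) <= 1e-9
    assert margin_of_error(0.5 * v[0] + 0.5 * v[1], v) <= 1e-9


def test_margin_analytic_two_sample_case():
    # projection of (1,0) onto segment [(0.8,0.2), (0.2,0.8)] hits the endpoint
    v = np.array([[0.8, 0.2], [0.2, 0.8]])
    d = margin_of_error(np.array([1.0, 0.0]), v)
    assert d == pytest.approx(np.sqrt(0.2 ** 2 + 0.2 ** 2), abs=1e-12)


def test_margin_dimension_mismatch_rejected():
    v = np.array([[0.5, 0.5], [0.9, 0.1]])
    with pytest.raises(ValueError, match="dimension"):
        margin_of_error(np.array([0.3, 0.3, 0.4]), v)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(0, 10_000), st.integers(2, 5), st.integers(3, 7))
def test_margin_nonnegative_order_invariant_zero_iff_inside(seed, K, J):
    rng = np.random.default_rng(seed)
    V = rng.dirichlet(np.ones(J), size=K)          # K vertices on the simplex
    inside = rng.dirichlet(np.ones(K)) @ V
    assert margin_of_error(inside, V) <= 1e-9
    g = rng.dirichlet(np.ones(J))
    d = margin_of_error(g, V)
    assert d >= 0.0
    perm = rng.permutation(K)
    assert margin_of_error(g, V[perm]) == pytest.approx(d, abs=1e-9)
    # distance certificate: margin equals ||g - V^T alpha|| at the minimizer
    dist, alpha = project_to_hull(g, V.T)
    assert alpha.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(alpha >= -1e-10)
    assert dist == pytest.approx(np.linalg.norm(V.T @ alpha - g), abs=1e-9)


def test_find_vertices_recovers_planted_simplex():
    rng = np.random.default_rng(12)
    A = rng.dirichlet(np.ones(3) * 2.0, size=6)     # J=6 samples, K=3
    vertices = (A / A.sum(axis=0)).T                # normalized columns
    interior = rng.dirichlet(np.ones(3), size=9) @ vertices
    centers = np.vstack([vertices, interior])
    model = find_vertices(_cluster_set(centers), K=3)
    assert set(model.vertex_cluster_indices) == {0, 1, 2}
    assert model.fit_error <= 1e-9
    np.testing.assert_allclose(model.A, A, atol=1e-9)


def test_find_vertices_forced_when_m_equals_k():
    rng = np.random.default_rng(13)
    centers = rng.dirichlet(np.ones(5), size=3)
    model = find_vertices(_cluster_set(centers), K=3)
    assert model.vertex_cluster_indices == (0, 1, 2)
    assert model.fit_error == 0.0


def test_find_vertices_skips_rank_deficient_candidates():
    v = np.array([[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]])
    centers = np.vstack([v, v[0]])                  # duplicate vertex center
    model = find_vertices(_cluster_set(centers), K=3)
    # any subset containing both copies of v[0] is rank-deficient; the
    # search must still return a full-rank minimizer
    assert len(set(model.vertex_cluster_indices)) == 3
    assert np.linalg.matrix_rank(model.A, tol=1e-8) == 3


def test_find_vertices_budget_guard():
    rng = np.random.default_rng(14)
    centers = rng.dirichlet(np.ones(9), size=40)
    with pytest.raises(ValueError, match="budget"):
        find_vertices(_cluster_set(centers), K=5, subset_budget=1e4)


def test_mixing_rescaling_round_trip():
    rng = np.random.default_rng(15)
    A = rng.dirichlet(np.ones(4), size=8)           # J=8, K=4, unit row sums
    normalized = (A / A.sum(axis=0)).T              # what vertex centers look like
    np.testing.assert_allclose(rescale_to_mixing(normalized), A, atol=1e-10)


def test_identify_markers_maps_vertex_cluster_members():
    v = np.array([[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8],
                  [1 / 3, 1 / 3, 1 / 3]])
    cs = ClusterSet(
        centers=v, exemplar_ids=["gA", "gC", "gE", "gF"],
        membership=np.array([0, 0, 1, 2, 3, 3]),
        sizes=np.array([2, 1, 1, 2]),
        gene_ids=["gA", "gB", "gC", "gE", "gF", "gG"],
    )
    model = find_vertices(cs, K=3)
    markers = identify_markers(model, cs)
    assert markers[0] == {"gA", "gB"}
    assert markers[1] == {"gC"}
    assert markers[2] == {"gE"}
    # interior-cluster genes appear in no marker set
    assert not any({"gF", "gG"} & s for s in markers.values())


def test_lemma1_containment_noise_free(tiny_noisefree):
    """Every mixed gene vector lies inside the hull of normalized mixing columns."""
    expr, truth = tiny_noisefree
    vec = sum_normalize(expr)
    vertices = (truth.A_true / truth.A_true.sum(axis=0)).T
    rng = np.random.default_rng(0)
    for i in rng.choice(vec.n_genes, size=40, replace=False):
        assert margin_of_error(vec.vectors[i], vertices) <= 1e-9
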