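"""Marker-based proportion estimation and NNLS profile recovery."""

import numpy as np
import pytest
from scipy.optimize import minimize

from camix import ExpressionMatrix, estimate_profiles, estimate_proportions, mix
from camix.deconvolve import standardized_marker_average


def _expr(values, gene_ids=None):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(gene_ids, [f"s{j}" for j in range(values.shape[1])],
                            values)


def test_standardized_average_single_marker_l1():
    expr = _expr([[3.0, 1.0], [1.0, 3.0]])
    cols = standardized_marker_average(expr, {0: {"g0"}, 1: {"g1"}}, "l1")
    np.testing.assert_allclose(cols[:, 0], [0.75, 0.25])
    np.testing.assert_allclose(cols[:, 1], [0.25, 0.75])


@pytest.mark.parametrize("norm", ["l1", "l2"])
def test_noise_free_proportions_exact(norm):
    rng = np.random.default_rng(31)
    K, J, N = 3, 7, 60
    A = rng.dirichlet(np.ones(K) * 2.0, size=J)
    S = np.zeros((N, K))
    markers = {}
    for k in range(K):
        idx = range(k * 5, k * 5 + 5)
        for i in idx:
            S[i, k] = rng.lognormal(2, 0.5)
        markers[k] = {f"g{i}" for i in idx}
    S[15:] = rng.dirichlet(np.ones(K), size=N - 15) * rng.lognormal(
        2, 0.5, size=(N - 15, 1))
    expr = mix(S, A, noise_sd=0.0, gene_ids=[f"g{i}" for i in range(S.shape[0])])
    A_hat = estimate_proportions(expr, markers, norm)
    np.testing.assert_allclose(A_hat, A, atol=1e-9)


def test_duplicated_marker_leaves_estimate_unchanged():
    expr1 = _expr([[3.0, 1.0], [1.0, 3.0]])
    expr2 = _expr([[3.0, 1.0], [6.0, 2.0], [1.0, 3.0]], ["g0", "g0b", "g1"])
    a1 = estimate_proportions(expr1, {0: {"g0"}, 1: {"g1"}})
    a2 = estimate_proportions(expr2, {0: {"g0", "g0b"}, 1: {"g1"}})
    np.testing.assert_allclose(a1, a2, atol=1e-12)


def test_empty_marker_set_names_subpopulation():
    expr = _expr([[1.0, 2.0]])
    with pytest.raises(ValueError, match="subpopulation 1"):
        estimate_proportions(expr, {0: {"g0"}, 1: set()})


def test_profiles_noise_free_exact():
    rng = np.random.default_rng(32)
    A = rng.dirichlet(np.ones(2) * 3.0, size=5)
    S = rng.lognormal(2, 1, size=(40, 2))
    expr = mix(S, A, noise_sd=0.0, gene_ids=[f"g{i}" for i in range(S.shape[0])])
    S_hat, resid = estimate_profiles(expr, A)
    np.testing.assert_allclose(S_hat, S, rtol=1e-6)
    assert np.all(resid <= 1e-9)


def test_profiles_zero_gene_gives_zero_row():
    A = np.array([[0.6, 0.4], [0.3, 0.7], [0.5, 0.5]])
    expr = _expr([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]])
    S_hat, resid = estimate_profiles(expr, A)
    np.testing.assert_array_equal(S_hat[0], 0.0)
    assert resid[0] == 0.0


def test_noisy_gene_matches_qp_oracle():
    rng = np.random.default_rng(33)
    A = rng.dirichlet(np.ones(2), size=4)
    x = rng.lognormal(1, 1, size=4)
    expr = _expr(x[None, :])
    S_hat, resid = estimate_profiles(expr, A)

    def f(s):
        return 0.5 * np.sum((A @ s - x) ** 2)

    oracle = minimize(f, np.ones(2), bounds=[(0, None)] * 2, method="L-BFGS-B",
                      options={"ftol": 1e-16, "gtol": 1e-12})
    np.testing.assert_allclose(S_hat[0], oracle.x, atol=1e-6)
    assert resid[0] == pytest.approx(np.linalg.norm(A @ oracle.x - x), abs=1e-8)


def test_underdetermined_j_less_than_k_refused():
    A = np.array([[0.5, 0.3, 0.2], [0.2, 0.5, 0.3]])  # J=2 < K=3
    expr = _expr([[1.0, 2.0]])
    with pytest.raises(ValueError, match="underdetermined"):
        estimate_profiles(expr, A)


def test_rank_deficient_mixing_refused():
    A = np.array([[0.5, 0.5], [0.3, 0.3], [0.2, 0.2]])
    expr = _expr([[1.0, 2.0, 3.0]])
    with pytest.raises(ValueError, match="rank"):
        estimate_profiles(expr, A)


def test_permutation_equivariance():
    rng = np.random.default_rng(34)
    A = rng.dirichlet(np.ones(3), size=6)
    S = rng.lognormal(2, 1, size=(30, 3))
    S[:9] = 0.0
    markers = {}
    for k in range(3):
        for i in range(k * 3, k * 3 + 3):
            S[i, k] = rng.lognormal(2, 0.5)
        markers[k] = {f"g{i}" for i in range(k * 3, k * 3 + 3)}
    expr = mix(S, A, noise_sd=0.0, gene_ids=[f"g{i}" for i in range(S.shape[0])])
    A_hat = estimate_proportions(expr, markers)
    perm = {0: markers[1], 1: markers[2], 2: markers[0]}
    A_perm = estimate_proportions(expr, perm)
    np.testing.assert_allclose(A_perm, A_hat[:, [1, 2, 0]], atol=1e-12)
    S1, _ = estimate_profiles(expr, A_hat)
    S2, _ = estimate_profiles(expr, A_hat[:, [1, 2, 0]])
    np.testing.assert_allclose(S2, S1[:, [1, 2, 0]], atol=1e-9)


def test_scale_consistency():
    rng = np.random.default_rng(35)
    A = rng.dirichlet(np.ones(2), size=5)
    S = rng.lognormal(1, 1, size=(20, 2))
    S[:3, 1] = 0.0
    S[3:6, 0] = 0.0
    markers = {0: {f"g{i}" for i in range(3)}, 1: {f"g{i}" for i in range(3, 6)}}
    expr = mix(S, A, noise_sd=0.0, gene_ids=[f"g{i}" for i in range(S.shape[0])])
    scaled = _expr(expr.values * 12.5)
    np.testing.assert_allclose(estimate_proportions(scaled, markers),
                               estimate_proportions(expr, markers), atol=1e-12)
    S1, _ = estimate_profiles(expr, A)
    S2, _ = estimate_profiles(scaled, A)
    np.testing.assert_allclose(S2, 12.5 * S1, rtol=1e-9, atol=1e-8)
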