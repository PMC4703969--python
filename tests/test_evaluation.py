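"""E1 cross-talk index, marker confusion, baselines, perturbations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import pearsonr

from camix import (
    compute_e1,
    estimate_profiles,
    fold_change_markers,
    marker_confusion,
    mix,
    perturb_proportions,
    perturb_signatures,
    supervised_profiles_baseline,
)


def _random_mixing(rng, J=6, K=3):
    return rng.dirichlet(np.ones(K) * 2.0, size=J)


def test_e1_zero_for_perfect_estimate():
    A = _random_mixing(np.random.default_rng(41))
    assert compute_e1(A, A) == pytest.approx(0.0, abs=1e-9)


def test_e1_invariant_to_permutation_and_positive_scaling():
    rng = np.random.default_rng(42)
    A = _random_mixing(rng)
    perm = rng.permutation(3)
    D = np.diag(rng.uniform(0.2, 5.0, size=3))
    assert compute_e1(A @ np.eye(3)[:, perm] @ D, A) == pytest.approx(0.0, abs=1e-9)


def test_e1_hand_computed_cross_talk_case():
    # choose A_hat = I-padded so that pinv(A_hat) @ A_true = [[1,1],[0,1]]
    A_hat = np.array([[1.0, 0.0], [0.0, 1.0]])
    A_true = A_hat @ np.array([[1.0, 1.0], [0.0, 1.0]])
    assert compute_e1(A_hat, A_true) == pytest.approx(2.0, abs=1e-12)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.integers(0, 10_000))
def test_e1_nonnegative(seed):
    rng = np.random.default_rng(seed)
    A_hat = _random_mixing(rng)
    A_true = _random_mixing(rng)
    assert compute_e1(A_hat, A_true) >= 0.0


def test_e1_rank_deficiency_rejected():
    A = np.array([[0.5, 0.5], [0.3, 0.3], [0.2, 0.2]])
    with pytest.raises(ValueError, match="rank"):
        compute_e1(A, A)


def test_marker_confusion_identity():
    truth = {0: {"a", "b"}, 1: {"c"}}
    sens, spec, venn = marker_confusion(truth, truth, set("abcdefgh"))
    assert (sens, spec) == (1.0, 1.0)
    assert venn == (3, 0, 0)


def test_marker_confusion_empty_prediction():
    truth = {0: {"a", "b"}}
    sens, spec, _ = marker_confusion({0: set()}, truth, set("abcdef"))
    assert (sens, spec) == (0.0, 1.0)


def test_marker_confusion_hand_counted():
    truth = {0: {"a", "b", "c", "d"}}
    predicted = {0: {"a", "b", "e"}}
    universe = set("abcdefghij")
    sens, spec, venn = marker_confusion(predicted, truth, universe)
    assert sens == pytest.approx(0.5)
    assert spec == pytest.approx(5 / 6)
    assert venn == (2, 1, 2)


def test_marker_confusion_aligns_permuted_labels():
    truth = {0: {"a", "b"}, 1: {"c", "d"}}
    predicted = {0: {"c", "d"}, 1: {"a", "b"}}  # labels swapped
    sens, spec, _ = marker_confusion(predicted, truth, set("abcdefgh"))
    assert (sens, spec) == (1.0, 1.0)


def test_marker_confusion_empty_truth_rejected():
    with pytest.raises(ValueError, match="empty truth"):
        marker_confusion({0: {"a"}}, {0: set()}, set("abc"))


def test_fold_change_markers_rules():
    S = np.array([[10.0, 0.0, 0.0],   # exclusive -> marker of 0
                  [4.0, 3.0, 3.0],    # 4 < 2*3 -> no label
                  [9.0, 4.0, 1.0],    # 9 >= 2*4 -> marker of 0
                  [0.0, 0.0, 0.0]])   # silent -> no label
    markers = fold_change_markers(S, fc_threshold=2.0)
    assert markers[0] == {0, 2}
    assert markers[1] == set() and markers[2] == set()


def test_fold_change_threshold_monotone_shrinkage():
    rng = np.random.default_rng(43)
    S = rng.lognormal(1, 1, size=(80, 3)) * (rng.random((80, 3)) > 0.3)
    prev = None
    for fc in (1.5, 2.0, 3.0, 5.0):
        sets = fold_change_markers(S, fc)
        pooled = set().union(*sets.values())
        if prev is not None:
            assert pooled <= prev
        prev = pooled


def test_supervised_baseline_exact_with_true_proportions():
    rng = np.random.default_rng(44)
    A = rng.dirichlet(np.ones(3), size=9)
    S = rng.lognormal(2, 1, size=(50, 3))
    expr = mix(S, A, noise_sd=0.0)
    S_hat, resid = supervised_profiles_baseline(expr, A)
    np.testing.assert_allclose(S_hat, S, rtol=1e-6)
    with pytest.raises(ValueError, match="underdetermined"):
        supervised_profiles_baseline(mix(S[:, :2], A[:1, :2], 0.0), A[:1])


def test_perturbed_proportions_degrade_marker_recovery_on_average():
    rng = np.random.default_rng(45)
    A = rng.dirichlet(np.ones(3) * 2.0, size=9)
    S = rng.lognormal(2, 1, size=(60, 3))
    marker_idx = np.arange(15)
    S[marker_idx] = 0.0
    for k in range(3):
        S[5 * k:5 * k + 5, k] = rng.lognormal(2, 0.5, size=5)
    expr = mix(S, A, noise_sd=0.0)
    mean_r = []
    for mag in (0.0, 0.1, 0.3):
        rs = []
        for seed in range(5):
            A_p = perturb_proportions(A, mag, seed=seed)
            S_hat, _ = estimate_profiles(expr, A_p)
            rs.append(np.mean([
                pearsonr(S_hat[marker_idx, k], S[marker_idx, k])[0]
                for k in range(3)
            ]))
        mean_r.append(np.mean(rs))
    assert mean_r[0] == pytest.approx(1.0, abs=1e-9)
    assert mean_r[0] >= mean_r[1] >= mean_r[2]


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 10_000), st.floats(0.0, 0.5))
def test_perturb_proportions_stays_on_simplex(seed, mag):
    rng = np.random.default_rng(seed)
    A = rng.dirichlet(np.ones(4), size=6)
    out = perturb_proportions(A, mag, seed=seed)
    assert np.all(out >= 0)
    np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-9)
    np.testing.assert_array_equal(out, perturb_proportions(A, mag, seed=seed))
    if mag == 0.0:
        np.testing.assert_array_equal(out, A)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 10_000), st.floats(0.0, 1.0))
def test_perturb_signatures_nonnegative_and_seeded(seed, pct):
    rng = np.random.default_rng(seed)
    S = rng.lognormal(1, 1, size=(12, 3))
    out = perturb_signatures(S, pct, seed=seed)
    assert np.all(out >= 0)
    np.testing.assert_array_equal(out, perturb_signatures(S, pct, seed=seed))
    if pct == 0.0:
        np.testing.assert_array_equal(out, S)
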