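"""Feature standardization, composite loss, k-fold splits, training-loop
behavior and the Dice/accuracy metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adgcn.model import ModelConfig, init_params, model_forward, predict_labels
from adgcn.synthetic import SyntheticSpec, make_dataset
from adgcn.train import (MetricsReport, TrainConfig, accuracy, dice, evaluate,
                         kfold_split, loss, mean_dice, standardize_features,
                         train)


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def test_standardize_basic_and_constant_channel():
    x = np.column_stack([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
    out = standardize_features(x)
    assert np.allclose(out.mean(axis=0), 0.0)
    assert out[:, 0].std() == pytest.approx(1.0)
    assert np.allclose(out[:, 1], 0.0)  # constant channel maps to zeros


@settings(derandomize=True, max_examples=30)
@given(st.integers(0, 2**31 - 1))
def test_standardize_idempotent(seed):
    x = np.random.default_rng(seed).standard_normal((20, 3)) * 7 + 2
    once = standardize_features(x)
    assert np.allclose(standardize_features(once), once, atol=1e-12)


def test_standardize_rejects_non_finite():
    with pytest.raises(ValueError, match="non-finite"):
        standardize_features(np.array([[np.inf, 0.0]]))


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def test_loss_perfect_onehot_near_zero():
    z = np.eye(4)
    assert loss(z, np.arange(4)) == pytest.approx(0.0, abs=1e-9)


def test_loss_uniform_is_log_k():
    k = 7
    z = np.full((10, k), 1.0 / k)
    assert loss(z, np.zeros(10, dtype=int)) == pytest.approx(np.log(k))


def test_loss_l2_term_and_lower_bound():
    params = init_params(ModelConfig(in_channels=2, hidden_widths=(4,),
                                     n_classes=3, se_enabled=False,
                                     long_skips=False), 0)
    z = np.full((5, 3), 1.0 / 3)
    labels = np.zeros(5, dtype=int)
    lam = 0.01
    w_sq = sum((a ** 2).sum() for n, a in params.weight_matrices())
    assert loss(z, labels, params, lam) == pytest.approx(np.log(3) + lam * w_sq)
    # zero weights -> pure cross-entropy
    for _, a in params.weight_matrices():
        a[...] = 0.0
    assert loss(z, labels, params, lam) == pytest.approx(np.log(3))
    assert loss(z, labels, params, lam) >= 0.0


def test_loss_masks_ignored_and_validates_labels():
    z = np.array([[1.0, 0.0], [0.5, 0.5]])
    assert loss(z, np.array([0, -1])) == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(ValueError, match="out of range"):
        loss(z, np.array([0, 5]))


# ---------------------------------------------------------------------------
# k-fold
# ---------------------------------------------------------------------------

def test_kfold_partition_properties():
    ids = [f"s{i}" for i in range(100)]
    splits = kfold_split(ids, 5, seed=3)
    tests = [set(te) for _, te in splits]
    assert all(len(t) == 20 for t in tests)
    assert set().union(*tests) == set(ids)
    for i in range(5):
        assert not tests[i] & set(splits[i][0])
        for j in range(i + 1, 5):
            assert not tests[i] & tests[j]


def test_kfold_determinism_and_seed_sensitivity():
    ids = [f"s{i}" for i in range(11)]
    assert kfold_split(ids, 5, 1) == kfold_split(ids, 5, 1)
    assert kfold_split(ids, 5, 1) != kfold_split(ids, 5, 2)
    sizes = sorted(len(te) for _, te in kfold_split(ids, 5, 1))
    assert sizes == [2, 2, 2, 2, 3]  # sizes differ by at most one
    with pytest.raises(ValueError, match="fewer subjects"):
        kfold_split(["a", "b"], 5)


def test_kfold_agrees_with_reference_splitter():
    """Same partition law as scikit-learn's shuffled KFold: equal coverage
    and balanced sizes on any permutation."""
    from sklearn.model_selection import KFold
    ids = list(range(23))
    ours = kfold_split(ids, 5, seed=0)
    ref = list(KFold(5, shuffle=True, random_state=0).split(ids))
    assert sorted(len(te) for _, te in ours) == sorted(len(te) for _, te in ref)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def test_dice_identities():
    g = np.array([0, 0, 1, 1, 2])
    assert dice(g, g, 0) == 1.0 and mean_dice(g, g) == 1.0
    p = np.array([1, 1, 2, 2, 0])  # cyclic relabeling: disjoint per class
    assert dice(g, p, 0) == 0.0
    assert accuracy(g, p) == 0.0  # full derangement


def test_dice_analytic_case():
    # |G_c| = 4, |P_c| = 6, overlap 3 -> 2*3/(4+6) = 0.6
    g = np.array([1] * 4 + [0] * 6)
    p = np.array([1] * 3 + [0] * 1 + [1] * 3 + [0] * 3)
    assert dice(g, p, 1) == pytest.approx(0.6)


def test_accuracy_three_of_four():
    assert accuracy([0, 1, 2, 3], [0, 1, 2, 0]) == 0.75


def test_metrics_errors():
    with pytest.raises(ValueError, match="no labeled vertices"):
        accuracy([-1, -1], [0, 1])
    with pytest.raises(ValueError, match="absent from both"):
        dice([0, 0], [0, 0], 3)
    with pytest.raises(ValueError, match="length"):
        accuracy([0], [0, 1])


@settings(derandomize=True, max_examples=40)
@given(st.integers(0, 2**31 - 1), st.integers(2, 5))
def test_dice_symmetry_and_bounds(seed, k):
    rng = np.random.default_rng(seed)
    g = rng.integers(0, k, 30)
    p = rng.integers(0, k, 30)
    for c in np.unique(np.concatenate([g, p])):
        d = dice(g, p, int(c))
        assert 0.0 <= d <= 1.0
        assert d == dice(p, g, int(c))
    assert 0.0 <= accuracy(g, p) <= 1.0


def test_evaluate_ground_truth_is_perfect():
    spec = SyntheticSpec(level=1, n_parcels=3, seed=5)
    subjects = make_dataset(2, spec)
    rep = evaluate(None, subjects, predictions=[s.labels for s in subjects])
    assert rep.mean_dice == 1.0 and rep.accuracy == 1.0


def test_evaluate_pooled_accuracy_is_vertex_weighted():
    spec = SyntheticSpec(level=1, n_parcels=3, seed=6)
    subjects = make_dataset(3, spec)
    rng = np.random.default_rng(0)
    preds = [np.where(rng.random(len(s.labels)) < 0.3,
                      rng.integers(0, 3, len(s.labels)), s.labels)
             for s in subjects]
    rep = evaluate(None, subjects, predictions=preds)
    # brute-force recount over the concatenated cohort
    g_all = np.concatenate([s.labels for s in subjects])
    p_all = np.concatenate(preds)
    assert rep.accuracy == pytest.approx(np.mean(g_all == p_all))
    counts = np.array([len(s.labels) for s in subjects])
    weighted = np.sum(np.array(rep.per_subject_accuracy) * counts) / counts.sum()
    assert rep.accuracy == pytest.approx(weighted)
    # micro-pooled dice equals dice of the concatenation
    for cls, d in rep.per_class_dice.items():
        assert d == pytest.approx(dice(g_all, p_all, cls))


def test_report_serializes_to_table():
    rep = MetricsReport({0: 1.0, 1: 0.5}, 0.75, 0.9, [0.9], 10, {})
    text = rep.to_table()
    assert "class\tdice" in text and "mean_dice\t0.75" in text


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

_TINY = SyntheticSpec(level=2, n_parcels=4, signal_strength=3.0, noise_sd=1.0,
                      smoothing_steps=2, subject_jitter=1.0, seed=3)
_SMALL_MODEL = ModelConfig(hidden_widths=(16, 32, 16), n_classes=4,
                           se_enabled=True, se_ratio=4, long_skips=True)


def test_zero_learning_rate_leaves_parameters_unchanged():
    ds = make_dataset(1, _TINY)
    tc = TrainConfig(learning_rate=0.0, epochs=2, seed=0)
    params0 = init_params(_SMALL_MODEL, tc.seed)
    before = {n: a.copy() for n, a in params0.trainable()}
    params, _ = train(ds, _SMALL_MODEL, tc)
    for n, a in params.trainable():
        assert np.array_equal(a, before[n])


def test_training_descends_and_overfits_single_subject():
    ds = make_dataset(1, SyntheticSpec(level=2, n_parcels=4, signal_strength=4.0,
                                       noise_sd=0.5, subject_jitter=0.0, seed=9))
    tc = TrainConfig(epochs=120, seed=1)
    params, history = train(ds, _SMALL_MODEL, tc)
    assert history[-1] < history[0]
    z = model_forward(ds[0].graph, standardize_features(ds[0].features), params)
    acc = accuracy(ds[0].labels, predict_labels(z))
    assert acc >= 0.99


def test_training_is_deterministic():
    ds = make_dataset(2, _TINY)
    tc = TrainConfig(epochs=3, seed=7)
    p1, h1 = train(ds, _SMALL_MODEL, tc)
    p2, h2 = train(ds, _SMALL_MODEL, tc)
    assert h1 == h2
    for (n1, a1), (n2, a2) in zip(p1.trainable(), p2.trainable()):
        assert np.array_equal(a1, a2)


def test_dice_nondecreasing_in_signal_strength():
    """Held-out Dice grows with the separation of parcel means: across
    signal strengths {0, 1, 3} at fixed seeds, at most one inversion of at
    most 0.02 is tolerated (training is stochastic)."""
    scores = []
    for strength in (0.0, 1.0, 3.0):
        spec = SyntheticSpec(level=2, n_parcels=4, signal_strength=strength,
                             noise_sd=1.0, smoothing_steps=2,
                             subject_jitter=1.0, seed=13)
        ds = make_dataset(4, spec)
        params, _ = train(ds[:3], _SMALL_MODEL, TrainConfig(epochs=80, seed=13))
        scores.append(evaluate(params, ds[3:]).mean_dice)
    inversions = [max(0.0, scores[i] - scores[i + 1]) for i in range(2)]
    assert sum(v > 0 for v in inversions) <= 1
    assert max(inversions) <= 0.02
    assert scores[2] > scores[0]


def test_training_rejects_empty_dataset():
    with pytest.raises(ValueError, match="empty"):
        train([], _SMALL_MODEL, TrainConfig(epochs=1))
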