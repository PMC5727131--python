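"""Boosting trainers: formula fidelity, classical bounds, oracles."""
import itertools

import numpy as np
import pytest

from cgmboost import (DataError, model_from_json, model_to_json, predict,
                      staged_errors, train, train_discrete, train_gentle,
                      train_modest, train_real)
from cgmboost.boosting import (BlockLearner, Stump, _best_stump,
                               fit_regression_stump, modest_block_outputs)
from conftest import xor_dataset


def random_dataset(rng, m=40, n_features=5):
    X = rng.normal(size=(m, n_features))
    y = np.where(X[:, 0] + 0.5 * rng.normal(size=m) > 0, 1, -1)
    if np.unique(y).size < 2:  # pragma: no cover - vanishingly unlikely
        y[0] = -y[0]
    return X, y


def exhaustive_best_stump(X, y, w):
    """Independent brute-force stump search (all midpoints × polarities)."""
    best_err, best = np.inf, None
    for f in range(X.shape[1]):
        values = np.unique(X[:, f])
        for a, b in zip(values, values[1:]):
            thr = (a + b) / 2
            for pol in (1, -1):
                pred = np.where(X[:, f] > thr, pol, -pol)
                err = w[pred != y].sum()
                if err < best_err - 1e-15:
                    best_err, best = err, (f, thr, pol)
    return best_err, best


# ---------------------------------------------------------------------------
# discrete AdaBoost
# ---------------------------------------------------------------------------


def test_alpha_zero_at_half_error():
    # two identical points with opposite labels: any stump errs on exactly
    # one of them, so ε = 1/2 and α = 0
    X = np.array([[0.0], [1.0]])
    y = np.array([1, -1])
    w = np.array([0.5, 0.5])
    # direct formula check at ε = 0.5
    assert 0.5 * np.log((1 - 0.5) / 0.5) == 0.0
    model = train_discrete(np.array([[0.0], [0.0], [1.0], [1.0]]),
                           np.array([1, -1, 1, -1]), T=1)
    assert model.epsilons[0] == pytest.approx(0.5)
    assert model.alphas[0] == pytest.approx(0.0)


def test_separable_data_stops_after_one_round():
    X = np.array([[0.0], [1.0], [2.0], [3.0]])
    y = np.array([-1, -1, 1, 1])
    model = train_discrete(X, y, T=50)
    assert model.n_rounds == 1 and model.stopped_early
    labels, _ = predict(model, X)
    np.testing.assert_array_equal(labels, y)


def test_xor_stumps_stuck_at_oracle_optimum():
    # the canonical 4-point XOR set is provably inexpressible by boosted
    # axis-aligned stumps: every stump errs on exactly half the uniform
    # weight, so alpha is 0 and the ensemble never improves on the
    # exhaustive-stump-enumeration optimum
    X, y = xor_dataset()
    w = np.full(4, 0.25)
    oracle_err, _ = exhaustive_best_stump(X, y, w)
    assert oracle_err == pytest.approx(0.5)
    model = train_discrete(X, y, T=10)
    errors = staged_errors(model, X, y)
    assert np.all(np.asarray(model.epsilons) == 0.5)
    assert errors[-1] == pytest.approx(oracle_err)


def test_single_round_equals_exhaustive_best_stump(rng):
    X, y = random_dataset(rng)
    w = np.full(len(y), 1.0 / len(y))
    model = train_discrete(X, y, T=1)
    stump = model.learners[0]
    ref_err, (f, thr, pol) = exhaustive_best_stump(X, y, w)
    assert model.epsilons[0] == pytest.approx(ref_err, abs=1e-12)
    assert (stump.feature_index, stump.polarity) == (f, pol)
    assert stump.threshold == pytest.approx(thr)


def test_weights_sum_to_one_every_round(rng):
    X, y = random_dataset(rng, m=60)
    for variant in ("discrete", "real", "gentle", "modest"):
        model = train(variant, X, y, T=15, record_weights=True)
        assert model.weight_history, variant
        for w in model.weight_history:
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(w >= 0)


def test_training_error_bound_product_of_2_sqrt_eps(rng):
    # classical AdaBoost bound: err_t <= prod_{s<=t} 2 sqrt(eps_s (1-eps_s))
    X, y = random_dataset(rng, m=50)
    model = train_discrete(X, y, T=30)
    errors = staged_errors(model, X, y)
    bound = np.cumprod(
        [2 * np.sqrt(e * (1 - e)) for e in model.epsilons])
    assert np.all(errors <= bound + 1e-12)
    # ... and the exponential form with the edge gamma_t = 1/2 - eps_t
    gammas = 0.5 - np.asarray(model.epsilons)
    exp_bound = np.exp(-2 * np.cumsum(gammas**2))
    assert np.all(errors <= exp_bound + 1e-12)


def test_single_class_input_rejected():
    with pytest.raises(DataError):
        train_discrete(np.array([[0.0], [1.0]]), np.array([1, 1]), T=5)


def test_training_is_deterministic(rng):
    X, y = random_dataset(rng)
    for variant in ("discrete", "real", "gentle", "modest"):
        a = train(variant, X, y, T=10)
        b = train(variant, X, y, T=10)
        assert model_to_json(a) == model_to_json(b), variant


# ---------------------------------------------------------------------------
# Real AdaBoost
# ---------------------------------------------------------------------------


def test_real_block_output_zero_for_balanced_block():
    bins = np.array([0, 0, 1, 1])
    y = np.array([1, -1, 1, 1])
    w = np.full(4, 0.25)
    p_pos = np.bincount(bins, weights=w * (y == 1), minlength=2)
    p_neg = np.bincount(bins, weights=w * (y == -1), minlength=2)
    eps_s = 1 / 16
    out = 0.5 * np.log((p_pos + eps_s) / (p_neg + eps_s))
    assert out[0] == 0.0  # equal class mass -> log(1)
    assert out[1] > 0


def test_real_separable_four_points():
    # feature 0 separates perfectly with 2 equal-frequency bins
    X = np.array([[0.0, 5.0], [1.0, 5.0], [10.0, 5.0], [11.0, 5.0]])
    y = np.array([-1, -1, 1, 1])
    model = train_real(X, y, T=1, n_bins=2)
    assert model.z_values[0] < 1.0
    labels, _ = predict(model, X)
    np.testing.assert_array_equal(labels, y)
    learner = model.learners[0]
    assert learner.feature_index == 0
    # hand-computed block outputs: pure blocks of mass 1/2, eps_s = 1/16
    expected = 0.5 * np.log((0.5 + 1 / 16) / (0.0 + 1 / 16))
    assert learner.bin_outputs[1] == pytest.approx(expected)
    assert learner.bin_outputs[0] == pytest.approx(-expected)


def test_real_z_matches_recomputation(rng):
    X, y = random_dataset(rng, m=50)
    model = train_real(X, y, T=10, n_bins=4)
    # replay training independently to recompute z_t = 2 sum_j sqrt(p+ p-)
    w = np.full(len(y), 1.0 / len(y))
    for t, learner in enumerate(model.learners):
        edges = np.asarray(learner.bin_edges)
        bins = np.searchsorted(edges, X[:, learner.feature_index], side="right")
        nb = len(edges) + 1
        p_pos = np.bincount(bins, weights=w * (y == 1), minlength=nb)
        p_neg = np.bincount(bins, weights=w * (y == -1), minlength=nb)
        z = 2 * np.sum(np.sqrt(p_pos * p_neg))
        assert model.z_values[t] == pytest.approx(z, abs=1e-12)
        h = np.asarray(learner.bin_outputs)[bins]
        w = w * np.exp(-y * h)
        w /= w.sum()


# ---------------------------------------------------------------------------
# Gentle AdaBoost
# ---------------------------------------------------------------------------


def test_gentle_stump_constant_labels():
    X = np.array([[0.0], [1.0], [2.0]])
    y = np.array([1.0, 1.0, 1.0])
    w = np.full(3, 1 / 3)
    stump = fit_regression_stump(X, y, w)
    assert stump.left_value == pytest.approx(1.0)
    assert stump.right_value == pytest.approx(1.0)


@pytest.mark.parametrize("w0", [0.1, 0.5, 0.9])
def test_gentle_stump_two_points_closed_form(w0):
    X = np.array([[0.0], [1.0]])
    y = np.array([1.0, -1.0])
    stump = fit_regression_stump(X, y, np.array([w0, 1 - w0]))
    assert stump.left_value == pytest.approx(1.0)
    assert stump.right_value == pytest.approx(-1.0)


def test_gentle_exponential_loss_non_increasing(rng):
    X, y = random_dataset(rng, m=50)
    model = train_gentle(X, y, T=25)
    stages = model.staged_scores(X)
    d1 = np.full(len(y), 1.0 / len(y))
    losses = [np.sum(d1 * np.exp(-y * stages[t])) for t in range(model.n_rounds)]
    losses = [np.sum(d1)] + losses  # F_0 = 0
    for a, b in zip(losses, losses[1:]):
        assert b <= a + 1e-12


# ---------------------------------------------------------------------------
# Modest AdaBoost
# ---------------------------------------------------------------------------


def test_modest_symmetric_block_is_zero():
    bins = np.array([0, 0, 0, 0])
    y = np.array([1, -1, 1, -1])
    w = np.full(4, 0.25)
    w_inv = (1 - w) / (1 - w).sum()
    out = modest_block_outputs(bins, 1, w, w_inv, y)
    assert out[0] == pytest.approx(0.0)


def test_modest_outputs_bounded(rng):
    X, y = random_dataset(rng, m=60)
    model = train_modest(X, y, T=20, n_bins=6)
    for learner in model.learners:
        assert np.all(np.abs(learner.bin_outputs) <= 1.0 + 1e-12)


def reference_modest(X, y, T, edges_list):
    """Independent re-implementation of the Modest variant for cross-check."""
    m = len(y)
    w = np.full(m, 1.0 / m)
    ensemble = []
    for _ in range(T):
        w_inv = 1.0 - w
        w_inv = w_inv / w_inv.sum()
        best = None
        for f, edges in enumerate(edges_list):
            bins = np.searchsorted(edges, X[:, f], side="right")
            nb = len(edges) + 1
            out = np.zeros(nb)
            gain = 0.0
            for j in range(nb):
                in_j = bins == j
                p_pos = w[in_j & (y == 1)].sum()
                p_neg = w[in_j & (y == -1)].sum()
                pb_pos = w_inv[in_j & (y == 1)].sum()
                pb_neg = w_inv[in_j & (y == -1)].sum()
                out[j] = p_pos * (1 - pb_pos) - p_neg * (1 - pb_neg)
                gain += out[j] * (p_pos - p_neg)
            if best is None or gain > best[0]:
                best = (gain, f, out, bins)
        gain, f, out, bins = best
        if gain <= 1e-12:
            break
        ensemble.append((f, out))
        w = w * np.exp(-y * out[bins])
        w /= w.sum()
    return ensemble


def test_modest_degenerates_on_exact_xor():
    # on exact XOR every block is class-balanced under every distribution,
    # so the margin gain is zero and no learner can be added
    X, y = xor_dataset()
    with pytest.raises(DataError):
        train_modest(X, y, T=8, n_bins=2)


def test_modest_matches_reference_on_small_fixture():
    # small fixture whose features carry partial (not pure) signal, so the
    # variant trains for several rounds and the cross-check is meaningful
    X = np.array([[0.0, 0.9], [0.2, 0.1], [0.45, 0.8],
                  [0.55, 0.3], [0.8, 0.7], [1.0, 0.2]])
    y = np.array([1, 1, -1, 1, -1, -1])
    model = train_modest(X, y, T=8, n_bins=2)
    # rebuild the same equal-frequency edges the trainer uses
    from cgmboost.boosting import _equal_frequency_edges
    edges_list = [_equal_frequency_edges(X[:, f], 2) for f in range(2)]
    ref = reference_modest(X, y, 8, edges_list)
    assert len(ref) == model.n_rounds
    for (f_ref, out_ref), learner in zip(ref, model.learners):
        assert f_ref == learner.feature_index
        np.testing.assert_allclose(out_ref, learner.bin_outputs, atol=1e-12)
    # and identical predictions on a probe grid
    probe = np.array(list(itertools.product([0.0, 0.4, 0.6, 1.0], repeat=2)))
    score_ref = np.zeros(len(probe))
    for f, out in ref:
        bins = np.searchsorted(edges_list[f], probe[:, f], side="right")
        score_ref += out[bins]
    _, score = predict(model, probe)
    np.testing.assert_allclose(score_ref, score, atol=1e-12)


# ---------------------------------------------------------------------------
# prediction, staging, serialization
# ---------------------------------------------------------------------------


def test_predict_single_stump_and_tie_rule():
    model_stump = train_discrete(
        np.array([[0.0], [1.0], [2.0], [3.0]]), np.array([-1, -1, 1, 1]), T=1)
    labels, _ = predict(model_stump, np.array([[5.0], [-1.0]]))
    np.testing.assert_array_equal(labels, [1, -1])
    # score exactly 0 -> +1
    zero_model = model_stump
    zero_model.alphas = np.zeros_like(zero_model.alphas)
    labels, scores = predict(zero_model, np.array([[0.5]]))
    assert scores[0] == 0.0 and labels[0] == 1


def test_predict_feature_count_mismatch():
    X, y = xor_dataset()
    model = train_discrete(X, y, T=3)
    with pytest.raises(DataError):
        predict(model, np.zeros((2, 5)))


def test_score_equals_learnerwise_sum(rng):
    X, y = random_dataset(rng)
    model = train_real(X, y, T=7, n_bins=4)
    _, scores = predict(model, X)
    manual = np.zeros(len(y))
    for alpha, learner in zip(model.alphas, model.learners):
        manual += alpha * learner.response(X)
    np.testing.assert_allclose(scores, manual, atol=1e-12)


def test_staged_errors_consistency(rng):
    X, y = random_dataset(rng)
    model = train_discrete(X, y, T=1)
    errs = staged_errors(model, X, y)
    assert errs.shape == (model.n_rounds,)
    model10 = train_gentle(X, y, T=10)
    errs10 = staged_errors(model10, X, y)
    labels, _ = predict(model10, X)
    assert errs10[-1] == pytest.approx(np.mean(labels != y))


def test_model_json_roundtrip(rng):
    X, y = random_dataset(rng)
    for variant in ("discrete", "real", "gentle", "modest"):
        model = train(variant, X, y, T=5)
        clone = model_from_json(model_to_json(model))
        np.testing.assert_allclose(
            predict(clone, X)[1], predict(model, X)[1], atol=0)
        assert model_to_json(clone) == model_to_json(model)
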