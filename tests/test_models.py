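"""Architecture arithmetic, forward correctness, gradients, training contract."""

import logging
import math

import numpy as np
import pytest

from gaitpersona._net import Network, bce_with_logits, sigmoid
from gaitpersona.models import (
    CNNGaitClassifier,
    NNGaitClassifier,
    TrainConfig,
    build_cnn,
    build_nn,
    cnn_forward,
    count_parameters,
    load_model,
    nn_forward,
    save_model,
    train,
    train_with_retries,
)


def blobs(n=200, seed=0, spread=2.0):
    """Two well-separated Gaussian clusters in feature space."""
    rng = np.random.default_rng(seed)
    half = n // 2
    X = np.concatenate(
        [
            rng.normal(-spread, 1.0, size=(half, 8)),
            rng.normal(+spread, 1.0, size=(n - half, 8)),
        ]
    )
    y = np.array([0] * half + [1] * (n - half))
    return X, y


class TestArchitecture:
    def test_nn_has_41_trainable_parameters(self):
        assert count_parameters(build_nn(0)) == 41

    def test_nn_hidden_layer_width_4(self):
        m = build_nn(1)
        assert m.net_.layers[0].W.shape == (8, 4)
        assert m.net_.layers[1].W.shape == (4, 1)

    def test_nn_init_deterministic(self):
        a, b = build_nn(5), build_nn(5)
        for pa, pb in zip(a.net_.parameters(), b.net_.parameters()):
            np.testing.assert_array_equal(pa, pb)

    def test_cnn_layer_output_lengths(self):
        """Shape-inference oracle: valid conv L-K+1, pool (L-s)//s+1."""
        m = build_cnn(0)
        x = np.zeros((1, 200, 3), dtype=np.float32)
        shapes = []
        for layer in m.net_.layers:
            x = layer.forward(x, False, None)
            shapes.append(x.shape[1])
        # conv32 -> pool -> dropout -> conv16 -> pool -> dropout -> flatten
        assert shapes[0] == 200 - 32 + 1 == 169
        assert shapes[1] == (169 - 3) // 3 + 1 == 56
        assert shapes[3] == 56 - 16 + 1 == 41
        assert shapes[4] == (41 - 3) // 3 + 1 == 13
        assert shapes[6] == 13 * 8 == 104

    def test_cnn_parameter_count_matches_layer_arithmetic(self):
        expected = (
            (32 * 3 * 8 + 8)  # conv1: kernel x in-ch x filters + bias
            + (16 * 8 * 8 + 8)  # conv2
            + (104 * 3 + 3)  # dense
            + (3 * 1 + 1)  # output
        )
        assert count_parameters(build_cnn(0)) == expected == 2127

    def test_cnn_init_deterministic(self):
        a, b = build_cnn(9), build_cnn(9)
        for pa, pb in zip(a.net_.parameters(), b.net_.parameters()):
            np.testing.assert_array_equal(pa, pb)

    def test_count_parameters_on_minimal_dense(self):
        from gaitpersona._net import Dense

        assert Network([Dense(1, 1)]).n_parameters() == 2


class TestForward:
    def test_nn_all_zero_weights_gives_half(self):
        m = build_nn(0)
        for p in m.net_.parameters():
            p[...] = 0.0
        assert nn_forward(m, np.zeros(8)) == pytest.approx(0.5)

    def test_nn_output_in_unit_interval(self, rng):
        m = build_nn(2)
        p = nn_forward(m, rng.normal(size=(50, 8)) * 10)
        assert ((p > 0) & (p < 1)).all()

    def test_nn_toy_forward_matches_hand_arithmetic(self):
        # one active hidden unit fed by two features, worked through two
        # sigmoids with plain math
        m = build_nn(0)
        W1, b1 = m.net_.layers[0].W, m.net_.layers[0].b
        W2, b2 = m.net_.layers[1].W, m.net_.layers[1].b
        W1[...] = 0.0
        W1[0, 0], W1[1, 0] = 0.5, -0.25
        b1[...] = 0.0
        b1[0] = 0.1
        W2[...] = 0.0
        W2[0, 0] = 2.0
        b2[...] = -1.0
        x = np.array([1.0, 2.0, 0, 0, 0, 0, 0, 0])
        h0 = 1.0 / (1.0 + math.exp(-(0.5 * 1.0 - 0.25 * 2.0 + 0.1)))
        # inactive hidden units sit at sigmoid(0) = 0.5 but carry zero weight
        expected = 1.0 / (1.0 + math.exp(-(2.0 * h0 - 1.0)))
        assert nn_forward(m, x) == pytest.approx(expected, abs=1e-12)

    def test_nn_rejects_wrong_feature_count(self):
        with pytest.raises(ValueError):
            nn_forward(build_nn(0), np.zeros(7))

    def test_cnn_output_in_unit_interval_and_deterministic(self, rng):
        m = build_cnn(3)
        w = rng.normal(size=(200, 3))
        p1, p2 = cnn_forward(m, w), cnn_forward(m, w)
        assert 0 < p1 < 1
        assert p1 == p2  # dropout disabled at inference

    def test_cnn_toy_forward_matches_hand_arithmetic(self):
        # single averaging filter propagates a constant v through conv,
        # pool and dense identity taps: output = sigmoid(v)
        m = build_cnn(0)
        conv1, _, _, conv2, _, _, _, dense, out = m.net_.layers
        for layer in (conv1, conv2, dense, out):
            layer.W[...] = 0.0
            layer.b[...] = 0.0
        conv1.W[:, :, 0] = 1.0 / (32 * 3)
        conv2.W[:, 0, 0] = 1.0 / 16
        dense.W[0, 0] = 1.0  # flat index 0 = position 0, channel 0
        out.W[0, 0] = 1.0
        v = 0.3
        window = np.full((200, 3), v)
        assert cnn_forward(m, window) == pytest.approx(
            1.0 / (1.0 + math.exp(-v)), rel=1e-6
        )

    def test_cnn_rejects_wrong_shape(self):
        with pytest.raises(ValueError):
            cnn_forward(build_cnn(0), np.zeros((100, 3)))


def _loss_and_grads(net, X, y):
    logits = net.forward_logits(X, train=False)
    loss = bce_with_logits(logits, y)
    net.backward_from_logits((sigmoid(logits) - y) / len(y))
    return loss, [g.copy() for g in net.gradients()]


def _finite_difference_check(net, X, y, eps=1e-6, rtol=1e-5):
    _, grads = _loss_and_grads(net, X, y)
    flat_idx = 0
    for p, g in zip(net.parameters(), grads):
        it = np.nditer(p, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = p[idx]
            p[idx] = orig + eps
            lp = bce_with_logits(net.forward_logits(X), y)
            p[idx] = orig - eps
            lm = bce_with_logits(net.forward_logits(X), y)
            p[idx] = orig
            fd = (lp - lm) / (2 * eps)
            denom = max(abs(fd), abs(g[idx]), 1e-4)
            assert abs(fd - g[idx]) / denom < rtol, (
                f"param block {flat_idx} entry {idx}: analytic {g[idx]} vs FD {fd}"
            )
        flat_idx += 1


class TestGradients:
    def test_nn_gradients_match_finite_differences(self, rng):
        m = NNGaitClassifier(random_state=0).initialize()
        X = rng.normal(size=(16, 8))
        y = rng.integers(0, 2, 16).astype(float)
        _finite_difference_check(m.net_, X, y)

    def test_cnn_gradients_match_finite_differences(self, rng):
        # reduced input length keeps the exhaustive parameter sweep quick
        m = CNNGaitClassifier(input_len=100, random_state=0)
        m.net_ = m._build_network()
        m.net_.init(np.random.default_rng(0))  # float64 for the FD sweep
        X = rng.normal(size=(4, 100, 3))
        y = rng.integers(0, 2, 4).astype(float)
        _finite_difference_check(m.net_, X, y)


class TestTraining:
    def test_separable_blobs_reach_high_accuracy(self):
        X, y = blobs(200)
        m, hist = train(
            NNGaitClassifier(standardize=False),
            X,
            y,
            TrainConfig(epochs=150, seed=1),
        )
        acc = np.mean(m.predict(X) == y)
        assert acc >= 0.99

    def test_zero_epochs_is_identity(self):
        X, y = blobs(40)
        m0 = build_nn(3)
        m1, hist = train(m0, X, y, TrainConfig(epochs=0, seed=3))
        for a, b in zip(m0.net_.parameters(), m1.net_.parameters()):
            np.testing.assert_array_equal(a, b)
        assert len(hist["loss"]) == 0

    def test_training_is_bitwise_reproducible(self):
        X, y = blobs(100)
        cfg = TrainConfig(epochs=20, seed=7)
        m1, h1 = train(NNGaitClassifier(), X, y, cfg)
        m2, h2 = train(NNGaitClassifier(), X, y, cfg)
        np.testing.assert_array_equal(h1["loss"], h2["loss"])
        for a, b in zip(m1.net_.parameters(), m2.net_.parameters()):
            np.testing.assert_array_equal(a, b)

    def test_single_class_data_rejected(self):
        X = np.zeros((10, 8))
        with pytest.raises(ValueError):
            train(build_nn(0), X, np.ones(10), TrainConfig())
        with pytest.raises(ValueError):
            NNGaitClassifier().fit(X, np.zeros(10))

    def test_loss_non_increasing_over_ten_epoch_blocks(self):
        X, y = blobs(200, seed=4)
        _, hist = train(
            NNGaitClassifier(standardize=False), X, y, TrainConfig(epochs=100, seed=2)
        )
        block_means = hist["loss"].reshape(10, 10).mean(axis=1)
        assert (np.diff(block_means) <= 1e-6).all()

    def test_predictions_invariant_to_eval_order(self, rng):
        X, y = blobs(100)
        m, _ = train(NNGaitClassifier(), X, y, TrainConfig(epochs=30, seed=0))
        perm = rng.permutation(len(X))
        np.testing.assert_array_equal(m.predict(X)[perm], m.predict(X[perm]))


class TestRetraining:
    def test_easy_data_trains_once(self):
        X, y = blobs(100)
        calls = []

        def build(seed):
            calls.append(seed)
            return NNGaitClassifier(standardize=False)

        cfg = TrainConfig(epochs=100, seed=0, stuck_threshold=0.6, max_retrains=5)
        m = train_with_retries(build, X, y, cfg)
        assert len(calls) == 1
        assert m.final_train_accuracy_ >= 0.6

    def test_stuck_attempts_use_distinct_seeds_and_warn(self, caplog):
        # constant features make every attempt predict one class: acc 0.5
        X = np.ones((40, 8))
        y = np.array([0, 1] * 20)
        calls = []

        def build(seed):
            calls.append(seed)
            return NNGaitClassifier(standardize=False)

        cfg = TrainConfig(epochs=3, seed=0, stuck_threshold=0.6, max_retrains=4)
        with caplog.at_level(logging.WARNING, logger="gaitpersona.models"):
            m = train_with_retries(build, X, y, cfg)
        assert len(calls) == 4
        assert len(set(calls)) == 4  # every retry reinitialises differently
        assert any("stuck" in r.message for r in caplog.records)
        assert m.final_train_accuracy_ < 0.6


class TestFineTuning:
    def test_zero_epoch_fine_tune_is_identity(self):
        X, y = blobs(60)
        m = NNGaitClassifier(epochs=20, random_state=0).fit(X, y)
        ft = m.fine_tuned(X, y, epochs=0)
        for a, b in zip(m.net_.parameters(), ft.net_.parameters()):
            np.testing.assert_array_equal(a, b)

    def test_fine_tune_rate_must_be_smaller(self):
        X, y = blobs(60)
        m = NNGaitClassifier(epochs=5, random_state=0).fit(X, y)
        with pytest.raises(ValueError):
            m.fine_tuned(X, y, learning_rate=m.learning_rate)

    def test_general_model_untouched_by_fine_tuning(self):
        X, y = blobs(60)
        m = NNGaitClassifier(epochs=20, random_state=0).fit(X, y)
        before = [p.copy() for p in m.net_.parameters()]
        preds_before = m.predict(X)
        m.fine_tuned(X, y, epochs=10)
        for a, b in zip(before, m.net_.parameters()):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(preds_before, m.predict(X))


class TestCheckpoint:
    @pytest.mark.parametrize("kind", ["nn", "cnn"])
    def test_roundtrip_bit_exact(self, kind, tmp_path, rng):
        if kind == "nn":
            X, y = blobs(60)
            m = NNGaitClassifier(epochs=10, random_state=1).fit(X, y)
            Xe = X
        else:
            Xe = rng.normal(size=(12, 200, 3))
            m = build_cnn(1)
        path = tmp_path / "model.json"
        save_model(m, path)
        m2 = load_model(path)
        for a, b in zip(m.net_.parameters(), m2.net_.parameters()):
            np.testing.assert_array_equal(a, b)
            assert a.dtype == b.dtype
        np.testing.assert_array_equal(
            m.predict_proba(Xe), m2.predict_proba(Xe)
        )
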