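"""Architecture shape, gradients, training loop and early stopping."""

import numpy as np
import pandas as pd
import pytest

from fallcnn import nn
from fallcnn.model import (
    FallDetectorCNN,
    FallDetectorResults,
    NetworkConfig,
    TrainConfig,
    build_network,
)
from fallcnn.trace_io import ADL, FALL


def closed_form_widths(w):
    """Independent width recursion: three pooled blocks then one unpooled."""
    out = []
    for _ in range(3):
        w = w // 5  # conv preserves width; pooling floors by 5
        out.append(w)
    out.append(w)  # final block convolves but does not pool
    return out


def labeled(x, y):
    return x, [FALL if v else ADL for v in y]


class TestShapes:
    @pytest.mark.parametrize("width", [125, 130, 251, 501, 753, 1001, 2047, 3003])
    def test_forward_widths_match_recursion(self, width):
        net = build_network(width)
        assert net.feature_widths() == closed_form_widths(width)

    def test_reference_input_shapes(self):
        net = build_network(1001)
        assert net.feature_widths() == [200, 40, 8, 8]
        assert net.fc.w.shape == (2, 8 * 128)

    def test_first_conv_parameter_count(self):
        net = build_network(1001)
        conv1 = net.layers[0]
        assert conv1.w.size + conv1.b.size == 5 * 1 * 16 + 16  # == 96

    def test_too_narrow_input_names_minimum(self):
        with pytest.raises(ValueError, match="minimum width"):
            build_network(3)

    def test_reordered_filters_rejected(self):
        with pytest.raises(ValueError, match="increase"):
            NetworkConfig(filters_per_block=(32, 16, 64, 128))

    def test_binary_head_enforced(self):
        with pytest.raises(ValueError):
            NetworkConfig(n_classes=3)


class TestGradients:
    def test_finite_difference_gradient_check(self, rng):
        net = build_network(130, seed=0, dropout_rate=0.0)
        x = rng.normal(5, 3, size=(4, 130))
        y = np.array([0, 1, 0, 1])

        logits = net.forward(x, train=True)
        _, d = nn.softmax_cross_entropy(logits, y)
        net.backward(d)

        def loss():
            return nn.softmax_cross_entropy(net.forward(x, train=True), y)[0]

        eps = 1e-5
        for p in net.parameters():
            val, g = p["value"], p["grad"]()
            idx = tuple(rng.integers(0, s) for s in val.shape)
            orig = val[idx]
            val[idx] = orig + eps
            lp = loss()
            val[idx] = orig - eps
            lm = loss()
            val[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert num == pytest.approx(g[idx], rel=5e-2, abs=1e-6)

    def test_softmax_rows_sum_to_one(self, rng):
        p = nn.softmax(rng.normal(0, 50, size=(64, 2)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(p >= 0)


class TestTraining:
    def separable(self, rng, n=40, width=130):
        y = np.arange(n) % 2
        x = rng.normal(10.0, 1.0, size=(n, width))
        x[y == 1, width // 2 - 3: width // 2 + 3] += 30.0  # central spike = fall
        return x, y

    def test_identical_seeds_identical_histories(self, rng):
        x, y = self.separable(rng)
        xw, yw = labeled(x, y)
        runs = []
        for _ in range(2):
            m = FallDetectorCNN(xw, xw[:10], train_labels=yw, val_labels=yw[:10],
                                train_config=TrainConfig(max_epochs=5))
            runs.append(m.fit(seed=42).history)
        pd.testing.assert_frame_equal(runs[0], runs[1])

    def test_different_seeds_differ(self, rng):
        x, y = self.separable(rng)
        xw, yw = labeled(x, y)
        hists = []
        for seed in (1, 2):
            m = FallDetectorCNN(xw, xw[:10], train_labels=yw, val_labels=yw[:10],
                                train_config=TrainConfig(max_epochs=3))
            hists.append(m.fit(seed=seed).history["train_loss"].to_numpy())
        assert not np.allclose(hists[0], hists[1])

    def test_epoch_count_never_exceeds_maximum(self, rng):
        x, y = self.separable(rng)
        xw, yw = labeled(x, y)
        m = FallDetectorCNN(xw, xw[:10], train_labels=yw, val_labels=yw[:10])
        res = m.fit(seed=0)
        assert res.n_epochs_run <= 20
        assert 1 <= res.best_epoch <= res.n_epochs_run

    def test_patience_stops_on_forced_degradation(self, rng):
        # validation labels are the inverse of the training labels, so the
        # validation loss rises as soon as the network starts learning
        x, y = self.separable(rng, n=32)
        xw, yw = labeled(x, y)
        _, yv = labeled(x, 1 - y)
        tc = TrainConfig(learning_rate=1e-2, dropout_rate=0.0)
        m = FallDetectorCNN(xw, x, train_labels=yw, val_labels=yv, train_config=tc)
        res = m.fit(seed=0)
        assert res.n_epochs_run < tc.max_epochs
        assert res.n_epochs_run == res.best_epoch + tc.validation_patience

    def test_memorization_capacity(self, rng):
        # the network can drive the training loss near zero on 64 random
        # windows with arbitrary labels (overfit-on-purpose check)
        x = rng.normal(9.81, 2.0, size=(64, 130))
        y = rng.integers(0, 2, size=64)
        xw, yw = labeled(x, y)
        tc = TrainConfig(learning_rate=2e-2, dropout_rate=0.0, l2_coefficient=0.0)
        m = FallDetectorCNN(xw, xw, train_labels=yw, val_labels=yw, train_config=tc)
        res = m.fit(seed=0)
        assert res.history["train_loss"].min() < 0.1

    def test_single_class_training_set_rejected(self, rng):
        x = rng.normal(size=(10, 130))
        with pytest.raises(ValueError, match="single class"):
            FallDetectorCNN(x, x, train_labels=[ADL] * 10, val_labels=[ADL] * 10)


class TestPredict:
    def untrained_results(self, width=130):
        net = build_network(width, seed=0, dropout_rate=0.0)
        hist = pd.DataFrame([{"epoch": 1, "train_loss": 0.7, "train_accuracy": 0.5,
                              "val_loss": 0.7, "val_accuracy": 0.5}])
        return FallDetectorResults(model=None, network=net, history=hist,
                                   best_epoch=1, seed=0)

    def test_probabilities_normalized(self, rng):
        res = self.untrained_results()
        proba = res.predict_proba(rng.normal(size=(8, 130)))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_exact_tie_resolves_to_fall(self, rng):
        # the zero-initialized head outputs identical logits before training
        res = self.untrained_results()
        assert res.predict(rng.normal(size=(5, 130))) == [FALL] * 5

    def test_width_mismatch_names_both_widths(self, rng):
        res = self.untrained_results(width=130)
        with pytest.raises(ValueError, match="140.*130"):
            res.predict(rng.normal(size=(3, 140)))

    def test_checkpoint_round_trip(self, tmp_path, rng):
        x = rng.normal(9.81, 3.0, size=(20, 130))
        y = np.arange(20) % 2
        x[y == 1] += 10
        xw, yw = x, [FALL if v else ADL for v in y]
        m = FallDetectorCNN(xw, xw, train_labels=yw, val_labels=yw,
                            train_config=TrainConfig(max_epochs=3))
        res = m.fit(seed=7)
        path = res.save(tmp_path / "ckpt.npz")
        back = FallDetectorResults.load(path)
        np.testing.assert_allclose(back.predict_proba(x), res.predict_proba(x),
                                   atol=1e-12)
        assert back.best_epoch == res.best_epoch
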