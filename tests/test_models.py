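"""Model construction, structural 1D-filter guarantees, training behaviour,
grouped cross-validation and batch classification."""

import numpy as np
import pytest

from vocscan.dataset import VocDataPoint
from vocscan.errors import ConfigError, DataError
from vocscan.nn import (ModelConfig, TrainedModel, build_model, classify_batch,
                        cross_validate, softmax, softmax_cross_entropy,
                        train_model)


def _toy_dataset(n_per_class=50, delta=16, C=8, n_participants=5, seed=0,
                 n_classes=2):
    """Well-separated classes: each has its own active channel set."""
    rng = np.random.default_rng(seed)
    points = []
    for label in range(n_classes):
        chans = np.arange(C) % n_classes == label
        for i in range(n_per_class):
            w = rng.random((delta, C)) * 0.05
            bump = np.exp(-0.5 * ((np.arange(delta) - delta / 2) / 2.0) ** 2)
            w[:, chans] += bump[:, None]
            w = (w - w.min()) / (w.max() - w.min())
            points.append(VocDataPoint(window=w.astype(np.float32), label=label,
                                       sample_id=f"S{i}",
                                       participant_id=f"P{i % n_participants}",
                                       source_start=0, center_mu=delta // 2))
    return points


def _small_cfg(**kw):
    defaults = dict(family="vgg_like", depth=4, filter_mode="1D", n_classes=2,
                    widths=(4, 4, 6), epochs=15, batch_size=16, seed=1)
    defaults.update(kw)
    return ModelConfig(**defaults)


class TestStructure:
    @pytest.mark.parametrize("family,depth,widths", [
        ("vgg_like", 4, (4, 4, 6)), ("vgg_like", 6, (4, 4, 6, 6, 8)),
        ("vgg_like", 8, None), ("resnet", 6, (4, 6)), ("densenet", 7, None),
    ])
    def test_1d_mode_never_mixes_mz_channels(self, family, depth, widths):
        cfg = ModelConfig(family=family, depth=depth, filter_mode="1D",
                          n_classes=3, widths=widths, growth=4, seed=0)
        net = build_model(cfg)
        assert net.conv_layers(), "expected convolution layers"
        for conv in net.conv_layers():
            assert conv.kernel_shape[1] == 1
        for pool in net.pool_layers():
            assert pool.pool_shape[1] == 1

    def test_2d_mode_uses_square_kernels(self):
        net = build_model(_small_cfg(filter_mode="2D"))
        assert any(c.kernel_shape == (3, 3) for c in net.conv_layers())
        assert all(p.pool_shape == (2, 2) for p in net.pool_layers())

    def test_vgg_depth_counts_conv_plus_fc(self):
        net = build_model(_small_cfg(depth=4))
        assert len(net.conv_layers()) == 3     # + softmax FC head = depth 4

    def test_unsupported_configs_rejected(self):
        with pytest.raises(ConfigError):
            ModelConfig(family="vgg_like", depth=5)
        with pytest.raises(ConfigError):
            ModelConfig(family="alexnet")
        with pytest.raises(ConfigError):
            ModelConfig(family="densenet", depth=9)


class TestOutputs:
    def test_softmax_normalisation_and_uniform_logits(self):
        rng = np.random.default_rng(0)
        p = softmax(rng.normal(size=(40, 31)))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.allclose(softmax(np.full((3, 31), 2.5)), 1 / 31)

    def test_untrained_model_outputs_distributions(self):
        net = build_model(_small_cfg(n_classes=5))
        probs = net.predict_proba(np.random.default_rng(1).random((7, 16, 8)))
        assert probs.shape == (7, 5)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs.max(axis=1) >= 1 / 5).all()

    def test_classify_batch_matches_brute_force_argmax(self):
        net = build_model(_small_cfg(n_classes=4))
        windows = np.random.default_rng(2).random((100, 16, 8)).astype(np.float32)
        labels, confs, probs = classify_batch(net, windows)
        for i in range(100):
            best, arg = -1.0, 0
            for j in range(4):
                if probs[i, j] > best:
                    best, arg = probs[i, j], j
            assert labels[i] == arg
            assert confs[i] == probs[i].max()


class TestTraining:
    def test_separable_toy_reaches_perfect_accuracy(self):
        points = _toy_dataset()
        cfg = _small_cfg(epochs=20)
        trained = train_model(build_model(cfg), points, cfg)
        assert trained.history[-1]["accuracy"] == 1.0
        assert len(trained.history) <= 20

    def test_loss_decreases_and_training_is_deterministic(self):
        points = _toy_dataset()
        cfg = _small_cfg(epochs=5)
        t1 = train_model(build_model(cfg), points, cfg)
        t2 = train_model(build_model(cfg), points, cfg)
        assert t1.history[-1]["loss"] <= t1.history[0]["loss"]
        assert t1.history[-1]["loss"] == t2.history[-1]["loss"]

    def test_label_and_normalisation_contracts(self):
        points = _toy_dataset(n_per_class=4)
        cfg = _small_cfg(epochs=1)
        bad_label = points[0].__class__(window=points[0].window, label=7,
                                        sample_id="S", participant_id="P",
                                        source_start=0, center_mu=0)
        with pytest.raises(DataError):
            train_model(build_model(cfg), points + [bad_label], cfg)
        unnorm = points[0].__class__(window=points[0].window * 50.0, label=1,
                                     sample_id="S", participant_id="P",
                                     source_start=0, center_mu=0)
        with pytest.raises(DataError):
            train_model(build_model(cfg), points + [unnorm], cfg)

    def test_save_load_round_trip(self, tmp_path):
        points = _toy_dataset(n_per_class=10)
        cfg = _small_cfg(epochs=2)
        trained = train_model(build_model(cfg), points, cfg)
        trained.save(tmp_path / "model")
        back = TrainedModel.load(tmp_path / "model")
        x = np.stack([p.window for p in points[:8]])
        assert np.allclose(back.predict_proba(x), trained.predict_proba(x))


class TestCrossValidation:
    def test_grouped_cv_no_leakage_and_high_accuracy(self):
        points = _toy_dataset(n_per_class=40, n_participants=5)
        cfg = _small_cfg(epochs=8)
        mean, sd, accs = cross_validate(points, cfg, k=5)
        assert len(accs) == 5
        assert mean >= 0.95

    def test_each_fold_validates_one_participant_when_k_equals_p(self):
        points = _toy_dataset(n_per_class=20, n_participants=5)
        # leakage is asserted inside cross_validate on every fold
        groups = np.array([p.participant_id for p in points])
        from sklearn.model_selection import GroupKFold
        for tr, va in GroupKFold(5).split(np.zeros(len(points)), groups=groups):
            assert len(set(groups[va])) == 1
            assert not set(groups[tr]) & set(groups[va])

    def test_too_few_participants_rejected(self):
        points = _toy_dataset(n_per_class=10, n_participants=3)
        with pytest.raises(ConfigError):
            cross_validate(points, _small_cfg(epochs=1), k=5)


def test_gradients_match_finite_differences_float64():
    """Backprop of every family agrees with float64 central differences."""
    rng = np.random.default_rng(0)
    for fam, depth, widths in [("vgg_like", 4, (4, 4, 6)),
                               ("resnet", 6, (4, 6)),
                               ("densenet", 7, None)]:
        cfg = ModelConfig(family=fam, depth=depth, filter_mode="1D", n_classes=3,
                          widths=widths, growth=4, seed=1)
        net = build_model(cfg)
        x = rng.random((2, 1, 12, 5))
        net.forward(x)    # materialise head
        for p in net.params():
            p.val = p.val.astype(np.float64)
            p.grad = np.zeros_like(p.val)
        y = np.array([0, 2])
        loss, dl = softmax_cross_entropy(net.forward(x, train=True), y)
        net.backward(dl)
        for p in net.params():
            flat, gflat = p.val.ravel(), p.grad.ravel()
            for i in range(0, flat.size, max(1, flat.size // 3)):
                eps, orig = 1e-6, flat[i]
                flat[i] = orig + eps
                l1, _ = softmax_cross_entropy(net.forward(x), y)
                flat[i] = orig - eps
                l2, _ = softmax_cross_entropy(net.forward(x), y)
                flat[i] = orig
                num = (l1 - l2) / (2 * eps)
                assert abs(gflat[i] - num) < 1e-5 * max(1.0, abs(num)), \
                    f"{fam}: analytic {gflat[i]} vs numeric {num}"
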