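import numpy as np
import pytest

from reflexloc import nn
from reflexloc.classifier import (
    ClassifierConfig,
    DEFAULT_INCEPTION_SPEC,
    build_inception_block,
    build_reference_network,
    load_model,
    predict_proba,
    save_model,
    train,
)

TINY = ClassifierConfig(
    input_frames=8, input_size=(12, 12), stem_pool=1,
    conv_channels=(4, 6, 8), epochs=12, batch_size=8, seed=3,
    learning_rate=3e-3,
)


def _phase_window(label: int, rng, cfg=TINY) -> np.ndarray:
    """Visually distinct windows per class: a bright bar whose row encodes
    the phase, plus noise."""
    L, (h, w) = cfg.input_frames, cfg.input_size
    x = rng.normal(0, 0.05, size=(L, h, w, 3))
    row = {0: 1, 1: h // 2, 2: h - 2}[label]
    x[:, row, :, :] += 0.9
    return np.clip(x, -1, 1).astype(np.float32)


def _samples(n_per_class, seed=0, cfg=TINY):
    rng = np.random.default_rng(seed)
    out = []
    for label in (0, 1, 2):
        out += [(_phase_window(label, rng, cfg), label)
                for _ in range(n_per_class)]
    return out


class TestInceptionBlock:
    def test_channel_concatenation_arithmetic(self):
        spec = (((1, 8),), ((1, 8),), ((3, 8),), ((3, 8),))
        block = build_inception_block(4, spec, np.random.default_rng(0))
        x = np.zeros((1, 4, 5, 6, 6), dtype=np.float32)
        assert block.forward(x).shape[1] == 32

    def test_shape_preserved_with_same_padding(self):
        block = build_inception_block(3, rng=np.random.default_rng(0))
        x = np.random.default_rng(1).normal(size=(2, 3, 7, 9, 9)).astype(np.float32)
        y = block.forward(x)
        assert y.shape[0] == 2 and y.shape[2:] == (7, 9, 9)

    def test_default_spec_has_four_branches_two_filter_sizes(self):
        assert len(DEFAULT_INCEPTION_SPEC) == 4
        sizes = {k for branch in DEFAULT_INCEPTION_SPEC for k, _ in branch}
        assert sizes == {1, 3}

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            build_inception_block(3, ())
        with pytest.raises(ValueError):
            build_inception_block(3, (((1, 0),),))

    def test_gradients_flow_through_block(self):
        block = build_inception_block(2, (((1, 2),), ((3, 2),)),
                                      np.random.default_rng(0))
        x = np.random.default_rng(1).normal(size=(1, 2, 4, 5, 5)).astype(np.float32)
        y = block.forward(x)
        dx = block.backward(np.ones_like(y))
        assert dx.shape == x.shape


class TestNumericalGradients:
    def test_conv3d_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        conv = nn.Conv3D(2, 3, (3, 3, 3), rng)
        x = rng.normal(size=(2, 2, 4, 5, 5)).astype(np.float64).astype(np.float32)
        dy = rng.normal(size=(2, 3, 4, 5, 5)).astype(np.float32)
        conv.forward(x)
        conv.backward(dy)
        W = conv.params["W"]
        eps = 1e-3
        idx = (1, 0, 2, 1, 0)
        w0 = W[idx]
        W[idx] = w0 + eps
        up = float((conv.forward(x) * dy).sum())
        W[idx] = w0 - eps
        dn = float((conv.forward(x) * dy).sum())
        W[idx] = w0
        conv.forward(x)
        conv.backward(dy)
        numeric = (up - dn) / (2 * eps)
        assert conv.grads["W"][idx] == pytest.approx(numeric, rel=2e-2)

    def test_full_network_loss_gradient(self):
        cfg = ClassifierConfig(input_frames=4, input_size=(6, 6), stem_pool=1,
                               conv_channels=(3, 4, 5), seed=0)
        rng = np.random.default_rng(0)
        net = build_reference_network(cfg, rng)
        x = rng.normal(size=(3, 3, 4, 6, 6)).astype(np.float32)
        y = np.array([0, 1, 2])
        logits = net.forward(x)
        loss0, dlogits = nn.cross_entropy(logits, y)
        net.backward(dlogits)
        lin = [l for l in net.iter_layers() if isinstance(l, nn.Linear)][0]
        idx = (2, 1)
        eps = 1e-3
        analytic = float(lin.grads["W"][idx])
        w0 = lin.params["W"][idx]
        lin.params["W"][idx] = w0 + eps
        up, _ = nn.cross_entropy(net.forward(x), y)
        lin.params["W"][idx] = w0 - eps
        dn, _ = nn.cross_entropy(net.forward(x), y)
        assert analytic == pytest.approx((up - dn) / (2 * eps), rel=1e-2, abs=1e-6)


class TestTraining:
    def test_loss_decreases_on_one_event_worth_of_windows(self):
        samples = _samples(9)  # 27 windows, 9 per class
        model = train(samples, TINY)
        losses = [rec["loss"] for rec in model.training_log]
        assert len(losses) == TINY.epochs
        assert losses[-1] < losses[0]

    def test_same_seed_identical_parameters_and_log(self):
        samples = _samples(5)
        m1 = train(samples, TINY)
        m2 = train(samples, TINY)
        assert m1.training_log == m2.training_log
        for l1, l2 in zip(m1.network.iter_layers(), m2.network.iter_layers()):
            for name in l1.params:
                assert np.array_equal(l1.params[name], l2.params[name])

    def test_separable_phases_reach_95pct_training_accuracy(self):
        samples = _samples(12)
        model = train(samples, TINY)
        correct = sum(
            int(model.predict_proba(w).argmax() == y) for w, y in samples
        )
        assert correct / len(samples) >= 0.95

    def test_shape_mismatch_rejected_before_training(self):
        bad = [(np.zeros((4, 12, 12, 3), dtype=np.float32), 0)]
        with pytest.raises(ValueError, match="shape"):
            train(bad, TINY)

    def test_bad_labels_rejected(self):
        w = np.zeros((TINY.input_frames, *TINY.input_size, 3), dtype=np.float32)
        with pytest.raises(ValueError, match="labels"):
            train([(w, 5)], TINY)

    def test_external_backend_not_trainable_here(self):
        cfg = ClassifierConfig(backend="external")
        with pytest.raises(ValueError, match="reference"):
            train(_samples(1), cfg)


@pytest.fixture(scope="module")
def model():
    return train(_samples(4), TINY)


class TestPredict:

    def test_probabilities_normalized(self, model):
        rng = np.random.default_rng(9)
        p = predict_proba(model, _phase_window(1, rng))
        assert p.shape == (3,)
        assert (p >= 0).all()
        assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_constant_zero_window_still_normalized(self, model):
        w = np.zeros((TINY.input_frames, *TINY.input_size, 3), dtype=np.float32)
        p = predict_proba(model, w)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_argmax_tie_breaks_to_lowest_class(self):
        assert int(np.argmax(np.array([0.4, 0.4, 0.2]))) == 0
        assert int(np.argmax(np.array([0.3, 0.35, 0.35]))) == 1

    def test_wrong_shape_rejected(self, model):
        with pytest.raises(ValueError, match="shape"):
            model.predict_proba(np.zeros((3, 12, 12, 3), dtype=np.float32))

    def test_save_load_round_trip(self, model, tmp_path):
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        rng = np.random.default_rng(2)
        w = _phase_window(2, rng)
        assert np.allclose(model.predict_proba(w), back.predict_proba(w))
        assert back.training_log == model.training_log


class TestConfig:
    def test_three_classes_enforced(self):
        with pytest.raises(ValueError):
            ClassifierConfig(n_classes=2)

    def test_unknown_backend_rejected(self):
        with pytest.raises(ValueError):
            ClassifierConfig(backend="i3d")
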