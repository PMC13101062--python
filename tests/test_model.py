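"""Network mechanics: gradients, training loop, priming → rehearsal handoff."""

import numpy as np
import pytest

from oraltriage import (
    ModelConfig,
    Samples,
    TrainConfig,
    build_model,
    predict,
    prime,
    rehearsal_train,
    train,
)
from oraltriage.model import TrainedModel
from oraltriage.nnet import cross_entropy, get_weights, softmax

TINY = dict(backbone="tiny_cnn", image_feature_dim=8, mlp_hidden_dim=6,
            mlp_out_dim=4, dropout=0.0)


def _toy_samples(n=20, size=8, n_risk=5, seed=0, signal=1.5):
    """Linearly separable toy: positive samples are uniformly brighter."""
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    wl = rng.normal(0, 0.3, (n, 3, size, size)) + signal * y[:, None, None, None]
    af = rng.normal(0, 0.3, (n, 3, size, size)) - signal * y[:, None, None, None]
    risk = rng.normal(0, 1, (n, n_risk))
    return Samples(wl=wl, af=af, risk=risk, y=y, site_ids=[f"s{i}" for i in range(n)])


def test_default_concatenated_feature_length():
    cfg = ModelConfig(n_risk_features=10)
    assert cfg.concat_dim == 1024 + 1024 + 32
    net = build_model(cfg)
    assert net.head.layers[-1].w.value.shape == (2080, 2)


def test_softmax_outputs_normalized():
    net = build_model(ModelConfig(n_risk_features=5, seed=1, **TINY))
    data = _toy_samples(6)
    probs = softmax(net.forward(data.wl, data.af, data.risk))
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert probs.shape == (6, 2)


def test_risk_vector_length_mismatch_raises():
    net = build_model(ModelConfig(n_risk_features=5, **TINY))
    data = _toy_samples(4, n_risk=7)
    with pytest.raises(ValueError, match="risk vector"):
        net.forward(data.wl, data.af, data.risk)


def test_gradients_match_finite_differences():
    cfg = ModelConfig(n_risk_features=3, seed=2, **TINY)
    net = build_model(cfg)
    data = _toy_samples(4, size=6, n_risk=3, seed=3)
    rng = np.random.default_rng(4)

    def loss_value():
        return cross_entropy(net.forward(data.wl, data.af, data.risk), data.y)[0]

    for p in net.params():
        p.grad[...] = 0.0
    loss, dlogits = cross_entropy(net.forward(data.wl, data.af, data.risk), data.y)
    net.backward(dlogits)
    eps = 1e-6
    params = net.params()
    for _ in range(8):
        p = params[int(rng.integers(len(params)))]
        idx = tuple(int(rng.integers(d)) for d in p.value.shape)
        orig = p.value[idx]
        p.value[idx] = orig + eps
        up = loss_value()
        p.value[idx] = orig - eps
        down = loss_value()
        p.value[idx] = orig
        numeric = (up - down) / (2 * eps)
        assert np.isclose(p.grad[idx], numeric, rtol=1e-4, atol=1e-6), p.name


def test_fusion_is_live_unless_mlp_path_ablated():
    net = build_model(ModelConfig(n_risk_features=6, seed=5, **TINY))
    data = _toy_samples(2, n_risk=6)
    base = net.forward(data.wl, data.af, data.risk)
    zeroed = net.forward(data.wl, data.af, np.zeros_like(data.risk))
    assert not np.allclose(base, zeroed)
    # ablate the head's MLP segment: the risk vector can no longer matter
    fdim = net.config.image_feature_dim
    net.head.layers[-1].w.value[2 * fdim :, :] = 0.0
    base = net.forward(data.wl, data.af, data.risk)
    zeroed = net.forward(data.wl, data.af, np.zeros_like(data.risk))
    assert np.allclose(base, zeroed)


class TestTrainingLoop:
    def test_zero_learning_rate_freezes_weights(self):
        net = build_model(ModelConfig(n_risk_features=5, seed=6, **TINY))
        before = get_weights(net.params())
        cfg = TrainConfig(max_epochs=2, min_epochs_before_stability=1, lr=0.0, seed=0)
        train(net, _toy_samples(10), _toy_samples(6, seed=1), cfg)
        after = get_weights(net.params())
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_single_epoch_history(self):
        net = build_model(ModelConfig(n_risk_features=5, seed=7, **TINY))
        cfg = TrainConfig(max_epochs=1, min_epochs_before_stability=1, lr=1e-3, seed=0)
        out = train(net, _toy_samples(10), _toy_samples(6, seed=1), cfg)
        assert len(out.history["train_loss"]) == 1
        assert out.selected_epoch == 0

    def test_separable_toy_improves_loss(self):
        net = build_model(ModelConfig(n_risk_features=5, seed=8, **TINY))
        cfg = TrainConfig(max_epochs=12, min_epochs_before_stability=12, lr=3e-3, seed=0)
        out = train(net, _toy_samples(20), _toy_samples(10, seed=1), cfg)
        assert out.history["train_loss"][max(out.selected_epoch, 1)] < out.history["train_loss"][0]
        assert out.history["val_auc"][out.selected_epoch] > 0.9

    def test_single_class_validation_warns_and_uses_loss(self):
        net = build_model(ModelConfig(n_risk_features=5, seed=9, **TINY))
        val = _toy_samples(6, seed=1)
        val.y[:] = 0
        cfg = TrainConfig(max_epochs=2, min_epochs_before_stability=1, lr=1e-3, seed=0)
        with pytest.warns(UserWarning, match="single-class"):
            out = train(net, _toy_samples(10), val, cfg)
        assert out.history["val_auc"] == [None, None]

    def test_class_composition_logged(self):
        net = build_model(ModelConfig(n_risk_features=5, seed=10, **TINY))
        cfg = TrainConfig(max_epochs=1, min_epochs_before_stability=1, lr=1e-3, seed=0)
        out = train(net, _toy_samples(10), _toy_samples(6, seed=1), cfg)
        assert out.history["train_class_counts"] == {"refer": 5, "do_not_refer": 5}


class TestPrimeAndRehearsal:
    def _prime(self, seed=0, epochs=3):
        cfg = ModelConfig(n_risk_features=5, seed=11, **TINY)
        tc = TrainConfig(max_epochs=epochs, min_epochs_before_stability=1,
                         lr=1e-3, seed=seed)
        return prime(_toy_samples(10), _toy_samples(6, seed=1), cfg, tc)

    def test_priming_moves_weights_and_is_deterministic(self):
        a = self._prime()
        b = self._prime()
        init = build_model(a.config)
        assert any(
            not np.array_equal(a.weights[p.name], p.value) for p in init.params()
        )
        assert all(np.array_equal(a.weights[k], b.weights[k]) for k in a.weights)
        assert a.stage == "priming"

    def test_rehearsal_initializes_from_primed_weights(self):
        primed = self._prime()
        tc = TrainConfig(max_epochs=2, min_epochs_before_stability=1, lr=1e-3, seed=2)
        out = rehearsal_train(primed, _toy_samples(12, seed=2), _toy_samples(6, seed=3), tc)
        assert out.stage == "rehearsal"
        assert all(
            np.array_equal(out.initial_weights[k], primed.weights[k])
            for k in primed.weights
        )

    def test_zero_epoch_rehearsal_is_identity(self):
        primed = self._prime()
        tc = TrainConfig(max_epochs=0, min_epochs_before_stability=0, lr=1e-3, seed=2)
        out = rehearsal_train(primed, _toy_samples(12, seed=2), _toy_samples(6, seed=3), tc)
        assert all(np.array_equal(out.weights[k], primed.weights[k]) for k in primed.weights)

    def test_missing_primed_model_rejected(self):
        tc = TrainConfig(max_epochs=1, min_epochs_before_stability=1)
        with pytest.raises(ValueError, match="primed"):
            rehearsal_train(None, _toy_samples(4), _toy_samples(4), tc)


class TestPredict:
    def test_probability_range_and_determinism(self):
        primed = TestPrimeAndRehearsal()._prime()
        data = _toy_samples(5, seed=4)
        p1 = predict(primed, data.wl, data.af, data.risk)
        p2 = predict(primed, data.wl, data.af, data.risk)
        assert np.all((p1 >= 0) & (p1 <= 1))
        assert np.array_equal(p1, p2)

    def test_raw_intensity_input_warns(self):
        primed = TestPrimeAndRehearsal()._prime()
        data = _toy_samples(2, seed=4)
        with pytest.warns(UserWarning, match="8-bit"):
            predict(primed, data.wl * 200, data.af, data.risk)

    def test_bundle_round_trip(self, tmp_path):
        primed = TestPrimeAndRehearsal()._prime()
        primed.save(tmp_path / "bundle")
        back = TrainedModel.load(tmp_path / "bundle")
        data = _toy_samples(4, seed=5)
        assert np.array_equal(
            predict(primed, data.wl, data.af, data.risk),
            predict(back, data.wl, data.af, data.risk),
        )
        assert back.stage == primed.stage and back.selected_epoch == primed.selected_epoch
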