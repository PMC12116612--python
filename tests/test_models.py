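"""Model builders: architecture contracts, gradients, and trainability."""

import numpy as np
import pytest

from semgcobb import ModelConfig, build_lstm, build_model, build_svr, build_tcn, build_tcn_lstm
from semgcobb.models import NeuralHandle

TINY = dict(
    dilations=(1, 2), kernel_size=2, n_filters=4, conv_dropout=0.0,
    lstm_units=6, n_lstm_layers=2, lstm_dropout=0.0, fc_nodes=(8,),
    static_nodes=(4,), tcn_pool=2, lstm_max_steps=16, seed=11,
)


def tiny_config(kind, **over):
    return ModelConfig(kind=kind, **{**TINY, **over})


def tiny_data(rng, n=6, c=8, t=32, s=5):
    return (rng.normal(size=(n, c, t)).astype(np.float32),
            rng.normal(size=(n, s)).astype(np.float32))


@pytest.mark.parametrize("kind", ["tcn_lstm", "tcn", "lstm"])
class TestNeuralContracts:
    def test_output_shape(self, kind, rng):
        ts, sv = tiny_data(rng)
        h = build_model(tiny_config(kind, n_outputs=3), (8, 32), 5)
        assert h.predict(ts, sv).shape == (6, 3)
        assert h.predict(ts[0], sv[0]).shape == (3,)

    def test_zero_weights_give_zero_predictions(self, kind, rng):
        ts, sv = tiny_data(rng)
        h = build_model(tiny_config(kind), (8, 32), 5)
        h.set_weights([np.zeros_like(w) for w in h.get_weights()])
        np.testing.assert_array_equal(h.predict(ts, sv), 0.0)

    def test_parameter_count_monotone_in_lstm_units(self, kind, rng):
        counts = [
            build_model(tiny_config(kind, lstm_units=u), (8, 32), 5).parameter_count
            for u in (128, 256, 512)
        ]
        if kind == "tcn":
            assert counts[0] == counts[1] == counts[2]  # no LSTM module
        else:
            assert counts[0] < counts[1] < counts[2]

    def test_batch_invariance(self, kind, rng):
        ts, sv = tiny_data(rng)
        h = build_model(tiny_config(kind), (8, 32), 5)
        batch = h.predict(ts, sv)
        singles = np.stack([h.predict(ts[i], sv[i]) for i in range(len(ts))])
        np.testing.assert_allclose(batch, singles, atol=2e-5)

    def test_kind_mismatch_rejected(self, kind, rng):
        wrong = {"tcn_lstm": build_tcn, "tcn": build_lstm, "lstm": build_tcn_lstm}[kind]
        with pytest.raises(ValueError, match="kind"):
            wrong(tiny_config(kind), (8, 32), 5)

    def test_finite_output_for_finite_input(self, kind, rng):
        ts, sv = tiny_data(rng)
        h = build_model(tiny_config(kind), (8, 32), 5)
        assert np.all(np.isfinite(h.predict(1e3 * ts, 1e3 * sv)))


def test_gradients_match_finite_differences(rng):
    """Backprop vs central finite differences, all branches, float64."""
    for kind in ("tcn_lstm", "tcn", "lstm"):
        cfg = tiny_config(kind, n_outputs=2, conv_dropout=0.0, lstm_dropout=0.0)
        h = NeuralHandle(cfg, (3, 12), 4, dtype=np.float64)
        ts = rng.normal(size=(4, 3, 12))
        sv = rng.normal(size=(4, 4))
        y = rng.normal(size=(4, 2))
        h._set_mode(True)
        err = h._forward(ts, sv) - y
        h._adam.zero_grad()
        h._backward((2.0 / err.size) * err)
        checked = 0
        for p in h._params:
            flat = p.value.reshape(-1)
            gflat = p.grad.reshape(-1)
            for idx in range(0, flat.size, max(1, flat.size // 3)):
                eps = 1e-6
                old = flat[idx]
                flat[idx] = old + eps
                h._set_mode(True)
                lp = np.mean((h._forward(ts, sv) - y) ** 2)
                flat[idx] = old - eps
                h._set_mode(True)
                lm = np.mean((h._forward(ts, sv) - y) ** 2)
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                assert gflat[idx] == pytest.approx(num, rel=1e-4, abs=1e-7), (kind, idx)
                checked += 1
        assert checked > 30


class TestReceptiveField:
    def test_dilated_stack_reach(self):
        """Gradient-probe oracle for the causal receptive field.

        Kernel 3 with dilations (2,4,8,16,32) reaches 2*(2+4+8+16+32)=124
        steps into the past: a 125-step window ending at the output step.
        """
        cfg = ModelConfig(kind="tcn", n_filters=8, conv_dropout=0.0, seed=2)
        assert cfg.receptive_field == 125
        h = NeuralHandle(cfg, (8, 300), 3)
        conv = h._ts.layers[0]  # the dilated conv stack
        conv.set_mode(False)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 300, 8)).astype(np.float32)
        base = conv.forward(x.copy())
        t0 = 260

        def probe(t_perturb):
            xp = x.copy()
            xp[0, t_perturb, :] += 1.0
            return np.abs(conv.forward(xp) - base)[0]

        d_inside = probe(t0 - 124)
        d_outside = probe(t0 - 125)
        assert d_inside[t0].max() > 0
        assert d_outside[t0].max() == 0
        # causality: perturbing t0 never reaches earlier outputs
        d_now = probe(t0)
        assert d_now[:t0].max() == 0

    def test_infeasible_receptive_field_rejected(self):
        with pytest.raises(ValueError, match="receptive field"):
            build_tcn(ModelConfig(kind="tcn"), (8, 100), 3)  # RF 125 > 100


def test_lstm_output_is_order_sensitive(rng):
    ts, sv = tiny_data(rng, n=8, t=16)
    y = rng.normal(size=8)
    h = build_model(tiny_config("lstm", learning_rate=0.01), (8, 16), 5)
    for _ in range(30):
        h.train_batch(ts, sv, y)
    pred = h.predict(ts, sv)
    flipped = h.predict(ts[:, :, ::-1].copy(), sv)
    assert not np.allclose(pred, flipped, atol=1e-4)


def test_lstm_hidden_dimension_matches_units(rng):
    h = build_model(tiny_config("lstm", lstm_units=6), (8, 16), 5)
    x = rng.normal(size=(2, 16, 8)).astype(np.float32)
    h._set_mode(False)
    out = h._ts.forward(x)
    assert out.shape == (2, 6)


@pytest.mark.parametrize("kind", ["tcn_lstm", "tcn", "lstm"])
def test_overfits_tiny_sample(kind, rng):
    """Gradient flow through both branches: 8 samples driven to
    train RMSE < 0.5 degrees within 500 steps, dropout off."""
    cfg = tiny_config(kind, dilations=(1, 2, 4), kernel_size=3, n_filters=8,
                      lstm_units=16, fc_nodes=(16,), learning_rate=0.01,
                      tcn_pool=4, seed=4)
    ts, sv = tiny_data(rng, n=8, t=40)
    y = rng.normal(loc=20.0, scale=5.0, size=8)
    h = build_model(cfg, (8, 40), 5)
    for _ in range(500):
        h.train_batch(ts, sv, y)
    train_rmse = np.sqrt(np.mean((h.predict(ts, sv).ravel() - y) ** 2))
    assert train_rmse < 0.5, (kind, train_rmse)


class TestSVR:
    def test_interpolates_duplicated_points(self, rng):
        X = np.repeat(rng.normal(size=(3, 7)), 4, axis=0)
        y = np.repeat(np.array([10.0, 20.0, 30.0]), 4)
        h = build_svr(ModelConfig(kind="svr", svr_c=100.0, svr_epsilon=0.1), 4, 3)
        h.fit(X, y)
        resid = np.abs(h.predict(flat=X).ravel() - y)
        assert resid.max() <= 0.1 + 1e-2  # the epsilon tube, to solver tolerance

    def test_deterministic_across_refits(self, rng):
        X = rng.normal(size=(20, 7))
        y = rng.normal(size=20)
        cfg = ModelConfig(kind="svr")
        a = build_svr(cfg, 4, 3).fit(X, y).predict(flat=X)
        b = build_svr(cfg, 4, 3).fit(X, y).predict(flat=X)
        np.testing.assert_array_equal(a, b)

    def test_feature_dim_mismatch_rejected(self, rng):
        h = build_svr(ModelConfig(kind="svr"), 4, 3)
        h.fit(rng.normal(size=(10, 7)), rng.normal(size=10))
        with pytest.raises(ValueError, match="feature dimension"):
            h.predict(flat=rng.normal(size=(5, 6)))

    def test_requires_svr_kind(self):
        with pytest.raises(ValueError, match="svr"):
            build_svr(ModelConfig(kind="tcn"), 4, 3)


def test_config_validation():
    with pytest.raises(ValueError, match="dilations"):
        ModelConfig(dilations=(4, 2)).validate()
    with pytest.raises(ValueError, match="dropout"):
        ModelConfig(conv_dropout=1.5).validate()
    with pytest.raises(ValueError, match="kind"):
        ModelConfig(kind="transformer").validate()


def test_parallel_branch_variant_runs(rng):
    ts, sv = tiny_data(rng)
    h = build_model(tiny_config("tcn_lstm", parallel_branches=True), (8, 32), 5)
    assert h.predict(ts, sv).shape == (6, 1)


def test_residual_variant_runs(rng):
    ts, sv = tiny_data(rng)
    h = build_model(tiny_config("tcn", residual_blocks=True), (8, 32), 5)
    assert h.predict(ts, sv).shape == (6, 1)


def test_checkpoint_round_trip(rng, tmp_path):
    from semgcobb import load_checkpoint, save_checkpoint

    ts, sv = tiny_data(rng)
    y = rng.normal(size=6)
    h = build_model(tiny_config("tcn_lstm", learning_rate=0.01), (8, 32), 5)
    for _ in range(5):
        h.train_batch(ts, sv, y)
    save_checkpoint(h, tmp_path / "ckpt", history={"train_loss": [1.0]})
    back = load_checkpoint(tmp_path / "ckpt")
    np.testing.assert_array_equal(back.predict(ts, sv), h.predict(ts, sv))
    assert back.config == h.config
    assert (tmp_path / "ckpt" / "history.json").exists()
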