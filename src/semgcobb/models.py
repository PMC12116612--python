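"""Builders for the four Cobb-angle regression models.

* ``tcn_lstm`` — the dual-branch hybrid: a stack of dilated causal
  convolution blocks (conv -> batch norm -> ReLU -> dropout, one block
  per dilation rate) feeds, after temporal average pooling, a stack of
  LSTM layers whose final hidden state is concatenated with a dense
  embedding of the static patient features and passed through fully
  connected layers to a linear output.
* ``tcn`` — the convolutional stack alone, with global average pooling
  over time in place of the LSTM module.
* ``lstm`` — the recurrent stack alone, fed the (strided) input series.
* ``svr`` — an RBF-kernel support vector regressor over a flat feature
  vector (per-channel RMS + static features), the shallow baseline.

All handles share one prediction contract so the evaluation harness can
treat them uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from . import nn

MODEL_KINDS = ("tcn_lstm", "tcn", "lstm", "svr")


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the model zoo and of training.

    The search grids of the training protocol live in
    :class:`semgcobb.train_eval.SearchSpace`; this class holds one point.
    """

    kind: str = "tcn_lstm"
    dilations: tuple[int, ...] = (2, 4, 8, 16, 32)
    kernel_size: int = 3
    n_filters: int = 32
    conv_dropout: float = 0.2
    lstm_units: int = 128
    n_lstm_layers: int = 2
    lstm_dropout: float = 0.2
    fc_nodes: tuple[int, ...] = (128, 64, 32)
    static_nodes: tuple[int, ...] = (32,)
    # temporal pooling between the TCN stack and the LSTM module
    tcn_pool: int = 20
    # cap on the sequence length fed to the LSTM-only model
    lstm_max_steps: int = 500
    learning_rate: float = 0.001
    batch_size: int = 16
    n_outputs: int = 1
    residual_blocks: bool = False
    parallel_branches: bool = False
    seed: int = 0
    # SVR baseline hyperparameters
    svr_c: float = 10.0
    svr_epsilon: float = 0.1
    svr_gamma: float | str = "scale"

    def validate(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if list(self.dilations) != sorted(set(self.dilations)):
            raise ValueError("dilations must be strictly increasing")
        if self.kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")
        for d in (self.conv_dropout, self.lstm_dropout):
            if not (0 <= d < 1):
                raise ValueError("dropout rates must lie in [0, 1)")

    @property
    def receptive_field(self) -> int:
        """Input steps visible to one output step of the dilated conv stack."""
        return 1 + (self.kernel_size - 1) * sum(self.dilations)


class NeuralHandle:
    """A trainable NumPy model with a uniform predict/train contract."""

    is_neural = True

    def __init__(self, config: ModelConfig, input_shape: tuple[int, int],
                 static_dim: int, dtype=np.float32):
        config.validate()
        self.config = config
        self.input_shape = tuple(input_shape)  # (channels, time)
        self.static_dim = static_dim
        self.dtype = dtype
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([config.seed, 5])))
        self._build(rng)
        self._params = [p for br in self._branches for p in br.params()]
        self._adam = nn.Adam(self._params, lr=config.learning_rate)

    # -- architecture ------------------------------------------------------

    def _conv_stack(self, rng, c_in: int) -> nn.Sequential:
        cfg = self.config
        layers: list[nn.Layer] = []
        for d in cfg.dilations:
            block = [
                nn.CausalConv1d(c_in, cfg.n_filters, cfg.kernel_size, d, rng, self.dtype),
                nn.BatchNorm(cfg.n_filters, dtype=self.dtype),
                nn.ReLU(),
                nn.Dropout(cfg.conv_dropout, rng),
            ]
            if cfg.residual_blocks:
                skip = (
                    None if c_in == cfg.n_filters
                    else nn.CausalConv1d(c_in, cfg.n_filters, 1, 1, rng, self.dtype)
                )
                layers.append(nn.Residual(nn.Sequential(block), skip))
            else:
                layers.extend(block)
            c_in = cfg.n_filters
        return nn.Sequential(layers)

    def _lstm_stack(self, rng, n_in: int) -> nn.Sequential:
        cfg = self.config
        layers: list[nn.Layer] = []
        for i in range(cfg.n_lstm_layers):
            last = i == cfg.n_lstm_layers - 1
            layers.append(nn.LSTM(n_in, cfg.lstm_units, rng,
                                  return_sequences=not last, dtype=self.dtype))
            if not last:
                layers.append(nn.Dropout(cfg.lstm_dropout, rng))
            n_in = cfg.lstm_units
        return nn.Sequential(layers)

    def _dense_stack(self, rng, n_in: int, nodes, n_out: int | None) -> nn.Sequential:
        layers: list[nn.Layer] = []
        for n in nodes:
            layers += [nn.Dense(n_in, n, rng, self.dtype), nn.ReLU()]
            n_in = n
        if n_out is not None:
            layers.append(nn.Dense(n_in, n_out, rng, self.dtype))
        return nn.Sequential(layers)

    def _build(self, rng) -> None:
        cfg = self.config
        c_in, t_len = self.input_shape
        if cfg.kind in ("tcn_lstm", "tcn") and cfg.receptive_field > t_len:
            raise ValueError(
                f"infeasible receptive field: {cfg.receptive_field} steps "
                f"exceed the input length {t_len}"
            )

        self._static = self._dense_stack(rng, self.static_dim, cfg.static_nodes, None)
        static_out = cfg.static_nodes[-1] if cfg.static_nodes else self.static_dim

        if cfg.kind == "tcn_lstm":
            self._ts = nn.Sequential([self._conv_stack(rng, c_in)])
            if cfg.parallel_branches:
                # TCN and LSTM read the input side by side
                self._ts.layers.append(nn.GlobalAvgPoolTime())
                stride = max(1, int(np.ceil(t_len / cfg.lstm_max_steps)))
                self._ts2 = nn.Sequential(
                    [nn.StrideTime(stride), self._lstm_stack(rng, c_in)]
                )
                ts_out = cfg.n_filters + cfg.lstm_units
            else:
                # sequential composition: TCN features feed the LSTM
                self._ts.layers.append(nn.AvgPoolTime(cfg.tcn_pool))
                self._ts.layers.append(self._lstm_stack(rng, cfg.n_filters))
                self._ts2 = None
                ts_out = cfg.lstm_units
        elif cfg.kind == "tcn":
            self._ts = nn.Sequential(
                [self._conv_stack(rng, c_in), nn.GlobalAvgPoolTime()]
            )
            self._ts2 = None
            ts_out = cfg.n_filters
        elif cfg.kind == "lstm":
            stride = max(1, int(np.ceil(t_len / cfg.lstm_max_steps)))
            self._ts = nn.Sequential([nn.StrideTime(stride), self._lstm_stack(rng, c_in)])
            self._ts2 = None
            ts_out = cfg.lstm_units
        else:
            raise ValueError(f"NeuralHandle cannot build kind {cfg.kind!r}")

        self._head = self._dense_stack(rng, ts_out + static_out, cfg.fc_nodes, cfg.n_outputs)
        self._branches = [b for b in (self._ts, self._ts2, self._static, self._head) if b]
        self._ts_out = ts_out
        self._static_out = static_out

    # -- forward / backward ------------------------------------------------

    def _set_mode(self, train: bool) -> None:
        for br in self._branches:
            br.set_mode(train)

    def _forward(self, ts: np.ndarray, static: np.ndarray) -> np.ndarray:
        # ts arrives [B, C, T]; the engine uses [B, T, C]
        x = np.ascontiguousarray(ts.transpose(0, 2, 1)).astype(self.dtype, copy=False)
        h1 = self._ts.forward(x)
        if self._ts2 is not None:
            h1 = np.concatenate([h1, self._ts2.forward(x)], axis=-1)
        s = self._static.forward(static.astype(self.dtype, copy=False))
        self._concat_dims = (h1.shape[-1], s.shape[-1])
        return self._head.forward(np.concatenate([h1, s], axis=-1))

    def _backward(self, dy: np.ndarray) -> None:
        dz = self._head.backward(dy)
        d1, _ = self._concat_dims
        dh1, ds = dz[:, :d1], dz[:, d1:]
        self._static.backward(ds)
        if self._ts2 is not None:
            k = self._ts_out - self.config.lstm_units  # conv part width
            self._ts.backward(dh1[:, :k])
            self._ts2.backward(dh1[:, k:])
        else:
            self._ts.backward(dh1)

    # -- public contract ---------------------------------------------------

    @property
    def parameter_count(self) -> int:
        return int(sum(p.value.size for p in self._params))

    def predict(self, ts: np.ndarray, static: np.ndarray,
                flat: np.ndarray | None = None, batch_size: int = 256) -> np.ndarray:
        ts = np.asarray(ts)
        static = np.asarray(static)
        single = ts.ndim == 2
        if single:
            ts = ts[None]
            static = static[None]
        self._set_mode(False)
        outs = [
            self._forward(ts[i : i + batch_size], static[i : i + batch_size])
            for i in range(0, ts.shape[0], batch_size)
        ]
        y = np.concatenate(outs, axis=0)
        return y[0] if single else y

    def train_batch(self, ts: np.ndarray, static: np.ndarray, y: np.ndarray) -> float:
        """One Adam step on the mean-squared-error loss; returns the loss."""
        y = np.asarray(y, dtype=self.dtype)
        if y.ndim == 1:
            y = y[:, None]
        self._set_mode(True)
        pred = self._forward(np.asarray(ts), np.asarray(static))
        err = pred - y
        loss = float(np.mean(err**2))
        self._adam.zero_grad()
        self._backward((2.0 / err.size) * err.astype(self.dtype))
        self._adam.step()
        return loss

    def evaluate(self, ts: np.ndarray, static: np.ndarray, y: np.ndarray) -> float:
        """Mean-squared error in eval mode (no dropout, running BN stats)."""
        pred = self.predict(ts, static)
        y = np.asarray(y)
        if y.ndim == 1:
            y = y[:, None]
        return float(np.mean((pred - y) ** 2))

    def _walk_layers(self):
        stack = list(self._branches)
        while stack:
            layer = stack.pop()
            yield layer
            if isinstance(layer, nn.Sequential):
                stack.extend(layer.layers)
            elif isinstance(layer, nn.Residual):
                stack.append(layer.inner)
                if layer.skip:
                    stack.append(layer.skip)

    def get_norm_state(self) -> list[np.ndarray]:
        """Running batch-norm statistics (not trainable parameters)."""
        out = []
        for layer in self._walk_layers():
            if isinstance(layer, nn.BatchNorm):
                out += [layer.run_mean.copy(), layer.run_var.copy()]
        return out

    def set_norm_state(self, state: list[np.ndarray]) -> None:
        it = iter(state)
        for layer in self._walk_layers():
            if isinstance(layer, nn.BatchNorm):
                layer.run_mean = next(it).copy()
                layer.run_var = next(it).copy()

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self._params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        if len(weights) != len(self._params):
            raise ValueError("weight list length mismatch")
        for p, w in zip(self._params, weights):
            if p.value.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p.value[...] = w


class SVRHandle:
    """RBF-kernel support vector regression over flat features.

    One independently fitted regressor per output; features standardised
    inside the pipeline.  Deterministic for fixed data and config.
    """

    is_neural = False

    def __init__(self, config: ModelConfig, static_dim: int, feature_dim: int):
        config.validate()
        if config.kind != "svr":
            raise ValueError(f"SVRHandle requires kind 'svr', got {config.kind!r}")
        self.config = config
        self.n_features = static_dim + feature_dim
        self._models: list | None = None

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.shape[-1] != self.n_features:
            raise ValueError(
                f"feature dimension mismatch: got {X.shape[-1]}, expected {self.n_features}"
            )
        return X

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SVRHandle":
        X = self._check(X)
        y = np.asarray(y, dtype=np.float64)
        if y.ndim == 1:
            y = y[:, None]
        cfg = self.config
        self._models = []
        for j in range(y.shape[1]):
            pipe = make_pipeline(
                StandardScaler(),
                SVR(kernel="rbf", C=cfg.svr_c, epsilon=cfg.svr_epsilon, gamma=cfg.svr_gamma),
            )
            pipe.fit(X, y[:, j])
            self._models.append(pipe)
        return self

    def predict(self, ts=None, static=None, flat=None) -> np.ndarray:
        if self._models is None:
            raise RuntimeError("SVR model is not fitted")
        X = flat if flat is not None else static
        X = self._check(X)
        single = X.ndim == 1
        if single:
            X = X[None]
        y = np.column_stack([m.predict(X) for m in self._models])
        if self.config.n_outputs == 1:
            y = y[:, :1]
        return y[0] if single else y

    @property
    def parameter_count(self) -> int:
        if self._models is None:
            return 0
        return int(sum(m[-1].support_vectors_.size + m[-1].dual_coef_.size
                       for m in self._models))


def build_tcn_lstm(config: ModelConfig, input_shape: tuple[int, int],
                   static_dim: int) -> NeuralHandle:
    """Dual-branch hybrid: dilated causal conv stack -> LSTM, fused with statics."""
    if config.kind != "tcn_lstm":
        raise ValueError(f"expected kind 'tcn_lstm', got {config.kind!r}")
    return NeuralHandle(config, input_shape, static_dim)


def build_tcn(config: ModelConfig, input_shape: tuple[int, int],
              static_dim: int) -> NeuralHandle:
    """Convolution-only arm: the LSTM module replaced by global average pooling."""
    if config.kind != "tcn":
        raise ValueError(f"expected kind 'tcn', got {config.kind!r}")
    return NeuralHandle(config, input_shape, static_dim)


def build_lstm(config: ModelConfig, input_shape: tuple[int, int],
               static_dim: int) -> NeuralHandle:
    """Recurrent-only arm: the (strided) input series feeds the LSTM stack."""
    if config.kind != "lstm":
        raise ValueError(f"expected kind 'lstm', got {config.kind!r}")
    return NeuralHandle(config, input_shape, static_dim)


def build_svr(config: ModelConfig, static_dim: int, feature_dim: int) -> SVRHandle:
    """Shallow baseline: RBF support vector regression on flat features."""
    return SVRHandle(config, static_dim, feature_dim)


def build_model(config: ModelConfig, input_shape: tuple[int, int],
                static_dim: int, feature_dim: int = 0):
    """Dispatch on ``config.kind``; the harness's single entry point."""
    if config.kind == "svr":
        return build_svr(config, static_dim, feature_dim)
    builder = {"tcn_lstm": build_tcn_lstm, "tcn": build_tcn, "lstm": build_lstm}[config.kind]
    return builder(config, input_shape, static_dim)


def save_checkpoint(handle: NeuralHandle, path, history: dict | None = None) -> None:
    """Write a neural model to a checkpoint directory.

    Layout: ``config.json`` (hyperparameters + input shape), ``weights.npz``
    (one array per parameter, in order) and optionally ``history.json``.
    The SVR baseline refits deterministically in seconds and is not
    checkpointed.
    """
    import dataclasses
    import json
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": dataclasses.asdict(handle.config),
        "input_shape": list(handle.input_shape),
        "static_dim": handle.static_dim,
    }
    (path / "config.json").write_text(json.dumps(meta, indent=1))
    np.savez(path / "weights.npz",
             **{f"p{i}": w for i, w in enumerate(handle.get_weights())},
             **{f"bn{i}": s for i, s in enumerate(handle.get_norm_state())})
    if history is not None:
        (path / "history.json").write_text(json.dumps(history, indent=1))


def load_checkpoint(path) -> NeuralHandle:
    """Rebuild a neural model from a checkpoint directory."""
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads((path / "config.json").read_text())
    cfg_kw = {k: (tuple(v) if isinstance(v, list) else v)
              for k, v in meta["config"].items()}
    handle = NeuralHandle(ModelConfig(**cfg_kw), tuple(meta["input_shape"]),
                          int(meta["static_dim"]))
    with np.load(path / "weights.npz") as z:
        n_p = sum(1 for f in z.files if f.startswith("p"))
        n_b = sum(1 for f in z.files if f.startswith("bn"))
        handle.set_weights([z[f"p{i}"] for i in range(n_p)])
        handle.set_norm_state([z[f"bn{i}"] for i in range(n_b)])
    return handle
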