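"""Dataset assembly, training protocol, cross-validation and benchmarking.

The protocol mirrors the study design: supervised samples are built per
(patient, exercise, week) — Cobb targets only at the radiographic weeks
0 and 24, the other outcomes at all four measurement weeks — and split
at *patient* granularity (7:3 train/test, with 10% of training patients
carved out as a validation set for early stopping), so no patient's
recordings leak across partitions.  Neural models train with Adam on
mean-squared error, batch size 16, at most 100 epochs with patience-10
early stopping and best-weight restoration.  Reporting follows the
benchmark-table layout: train/test RMSE and R^2 per week stratum and
overall, mean +/- sd over the folds of a 3-fold patient-level
cross-validation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import COBB_WEEKS, MEASUREMENT_WEEKS, Cohort
from .models import ModelConfig, build_model
from .preprocess import (
    MUSCLE_PAIRS,
    PAIR_REGION,
    FilterSpec,
    TensorSpec,
    _fit_length,
    _resample,
    bandpass_filter,
    static_vector,
)
from .preprocess import pmsi as _pmsi_ratio

TARGET_NAMES = ("cobb_T", "cobb_L", "art_T", "art_L", "srs22", "bst")

#: weeks at which each target is labelled
TARGET_WEEKS = {name: (COBB_WEEKS if name.startswith("cobb") else MEASUREMENT_WEEKS)
                for name in TARGET_NAMES}


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------


@dataclass
class SupervisedDataset:
    """Array-of-structs container for one prediction task.

    ``X_ts`` [N, 8, L] filtered/resampled series, ``X_static`` [N, S] the
    static vector (sex, BMI, multi-week PMSI), ``X_flat`` [N, 8 + S] the
    shallow-model features (per-channel RMS + static vector).
    """

    target_name: str
    X_ts: np.ndarray
    X_static: np.ndarray
    X_flat: np.ndarray
    y: np.ndarray
    patient_ids: np.ndarray
    weeks: np.ndarray
    exercises: np.ndarray

    def __len__(self) -> int:
        return len(self.y)

    @property
    def patients(self) -> np.ndarray:
        return np.unique(self.patient_ids)

    def subset(self, idx: np.ndarray) -> "SupervisedDataset":
        return SupervisedDataset(
            self.target_name, self.X_ts[idx], self.X_static[idx], self.X_flat[idx],
            self.y[idx], self.patient_ids[idx], self.weeks[idx], self.exercises[idx],
        )

    def subset_patients(self, patients) -> "SupervisedDataset":
        return self.subset(np.isin(self.patient_ids, list(patients)))


def make_supervised_samples(
    cohort: Cohort,
    target_name: str,
    tensor_spec: TensorSpec = TensorSpec(),
    filter_spec: FilterSpec = FilterSpec(),
) -> SupervisedDataset:
    """Assemble one sample per (patient, exercise, labelled week).

    The static vector carries the PMSI values of that exercise's
    recordings at all measurement weeks up to and including the sample's
    week (no future leakage).  Raises if a required label is missing.
    """
    if target_name not in TARGET_NAMES:
        raise ValueError(f"unknown target {target_name!r}")
    weeks_needed = TARGET_WEEKS[target_name]

    statics = {s.patient_id: s for s in cohort.statics}
    panels = {o.patient_id: o for o in cohort.outcomes}

    # one filtering pass per recording: tensor + RMS + PMSI together
    prepared: dict[tuple, dict] = {}
    for rec in cohort.recordings:
        st = statics[rec.patient_id]
        tensor_spec.validate(rec.sample_rate_hz)
        filt = bandpass_filter(rec.signals, rec.sample_rate_hz, filter_spec)
        rms_vals = np.sqrt(np.mean(np.square(filt.astype(np.float64)), axis=-1))
        pmsis = {}
        for pair, (chL, chR) in MUSCLE_PAIRS.items():
            convex = st.convex_side[PAIR_REGION[pair]]
            cvx, ccv = (chL, chR) if convex == "L" else (chR, chL)
            pmsis[pair] = _pmsi_ratio(rms_vals[cvx.value], rms_vals[ccv.value])
        ts = _resample(filt.astype(np.float64), rec.sample_rate_hz, tensor_spec.target_rate_hz)
        ts = _fit_length(ts, tensor_spec.target_len)
        if tensor_spec.normalization == "per_channel_zscore":
            mu = ts.mean(axis=-1, keepdims=True)
            sd = ts.std(axis=-1, keepdims=True)
            sd[sd == 0] = 1.0
            ts = (ts - mu) / sd
        prepared[(rec.patient_id, rec.exercise.name, rec.week)] = {
            "ts": ts.astype(np.float32), "rms": rms_vals, "pmsi": pmsis,
        }

    rows_ts, rows_sv, rows_flat, rows_y, rows_pid, rows_w, rows_ex = ([] for _ in range(7))
    seen = set()
    keys = sorted({(k[0], k[1]) for k in prepared})
    for pid, ex in keys:
        history = {
            w: prepared[(pid, ex, w)]["pmsi"]
            for w in MEASUREMENT_WEEKS
            if (pid, ex, w) in prepared
        }
        for w in weeks_needed:
            if (pid, ex, w) not in prepared:
                raise ValueError(f"missing recording for ({pid}, week {w}, {ex})")
            label = panels[pid].value(w, target_name)
            if label is None:
                raise ValueError(f"missing {target_name} label for {pid} at week {w}")
            key = (pid, w, ex, target_name)
            if key in seen:
                raise ValueError(f"duplicate sample key {key}")
            seen.add(key)
            entry = prepared[(pid, ex, w)]
            sv = static_vector(statics[pid], w, history)
            rows_ts.append(entry["ts"])
            rows_sv.append(sv.astype(np.float32))
            rows_flat.append(np.concatenate([entry["rms"], sv]).astype(np.float32))
            rows_y.append(label)
            rows_pid.append(pid)
            rows_w.append(w)
            rows_ex.append(ex)

    return SupervisedDataset(
        target_name=target_name,
        X_ts=np.stack(rows_ts),
        X_static=np.stack(rows_sv),
        X_flat=np.stack(rows_flat),
        y=np.asarray(rows_y, dtype=np.float64),
        patient_ids=np.asarray(rows_pid),
        weeks=np.asarray(rows_w),
        exercises=np.asarray(rows_ex),
    )


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainSpec:
    """Training-protocol constants."""

    max_epochs: int = 100
    patience: int = 10
    train_frac: float = 0.7
    val_frac_of_train: float = 0.1
    seed: int = 0
    group_by_patient: bool = True

    def validate(self) -> None:
        if not (0 < self.train_frac < 1):
            raise ValueError("train_frac must be in (0, 1)")
        if self.patience > self.max_epochs:
            raise ValueError("patience cannot exceed max_epochs")


def split_dataset(
    ds: SupervisedDataset, spec: TrainSpec
) -> tuple[SupervisedDataset, SupervisedDataset, SupervisedDataset]:
    """7:3 train/test split at patient granularity, with a validation
    carve-out (10% of training patients) for early stopping.

    With ``group_by_patient`` off, the split is at sample level (the
    potentially leaky protocol, kept for comparison).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if spec.group_by_patient:
        patients = ds.patients.copy()
        if len(patients) < 3:
            raise ValueError("need at least 3 patients for a grouped split")
        rng.shuffle(patients)
        n_train = int(np.floor(spec.train_frac * len(patients)))
        n_val = max(1, int(round(spec.val_frac_of_train * n_train)))
        train_p = patients[:n_train]
        test_p = patients[n_train:]
        val_p = train_p[:n_val]
        fit_p = train_p[n_val:]
        return (ds.subset_patients(fit_p), ds.subset_patients(val_p),
                ds.subset_patients(test_p))
    idx = rng.permutation(len(ds))
    n_train = int(np.floor(spec.train_frac * len(ds)))
    n_val = max(1, int(round(spec.val_frac_of_train * n_train)))
    return (ds.subset(idx[n_val:n_train]), ds.subset(idx[:n_val]),
            ds.subset(idx[n_train:]))


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def rmse(y: np.ndarray, y_pred: np.ndarray) -> float:
    """Root-mean-square error sqrt(mean((y - y_pred)^2))."""
    y = np.asarray(y, dtype=np.float64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.float64).ravel()
    if y.shape != y_pred.shape or y.size == 0:
        raise ValueError("rmse requires equal, nonzero-length inputs")
    return float(np.sqrt(np.mean((y - y_pred) ** 2)))


def r2(y: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    y = np.asarray(y, dtype=np.float64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.float64).ravel()
    if y.shape != y_pred.shape or y.size == 0:
        raise ValueError("r2 requires equal, nonzero-length inputs")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("r2 undefined for constant y")
    ss_res = float(np.sum((y - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------


def train_model(
    handle,
    train: SupervisedDataset,
    val: SupervisedDataset,
    spec: TrainSpec = TrainSpec(),
) -> dict:
    """Fit a model handle; returns the training history.

    Neural handles: mini-batch Adam on MSE, early stopping on validation
    loss (halt after ``patience`` epochs without improvement, restore the
    best weights).  SVR handles fit in one shot.
    """
    spec.validate()
    if len(train) == 0 or len(val) == 0:
        raise ValueError("train and validation sets must be nonempty")
    if not handle.is_neural:
        handle.fit(train.X_flat, train.y)
        pred = handle.predict(flat=val.X_flat)
        return {"train_loss": [], "val_loss": [float(np.mean((pred.ravel() - val.y) ** 2))],
                "stopped_epoch": 0, "best_epoch": 0}

    rng = np.random.default_rng(spec.seed)
    bs = handle.config.batch_size
    best_val = np.inf
    best_weights = (handle.get_weights(), handle.get_norm_state())
    best_epoch = 0
    history = {"train_loss": [], "val_loss": []}
    for epoch in range(1, spec.max_epochs + 1):
        order = rng.permutation(len(train))
        losses = []
        for i in range(0, len(order), bs):
            b = order[i : i + bs]
            loss = handle.train_batch(train.X_ts[b], train.X_static[b], train.y[b])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(lr={handle.config.learning_rate}); aborting"
                )
            losses.append(loss)
        val_loss = handle.evaluate(val.X_ts, val.X_static, val.y)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(float(val_loss))
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = (handle.get_weights(), handle.get_norm_state())
            best_epoch = epoch
        elif epoch - best_epoch >= spec.patience:
            break
    handle.set_weights(best_weights[0])
    handle.set_norm_state(best_weights[1])
    history["stopped_epoch"] = len(history["val_loss"])
    history["best_epoch"] = best_epoch
    return history


def _predict_ds(handle, ds: SupervisedDataset) -> np.ndarray:
    if handle.is_neural:
        return handle.predict(ds.X_ts, ds.X_static).ravel()
    return handle.predict(flat=ds.X_flat).ravel()


def fit_and_score(
    ds: SupervisedDataset,
    config: ModelConfig,
    spec: TrainSpec = TrainSpec(),
    tensor_shape: tuple[int, int] | None = None,
) -> dict:
    """The 7:3 protocol on one split: fit, then metrics per week stratum.

    Returns {"history", "strata": {stratum: {split: {rmse, r2, n}}},
    "predictions": DataFrame}.
    """
    train, val, test = split_dataset(ds, spec)
    handle = build_model(
        config,
        tensor_shape or ds.X_ts.shape[1:],
        ds.X_static.shape[1],
        feature_dim=ds.X_flat.shape[1] - ds.X_static.shape[1],
    )
    history = train_model(handle, train, val, spec)
    out = {"history": history, "strata": {}, "handle": handle}
    pred_rows = []
    for split_name, part in (("train", train), ("test", test)):
        pred = _predict_ds(handle, part)
        for stratum in [*TARGET_WEEKS[ds.target_name], "Total"]:
            mask = np.ones(len(part), bool) if stratum == "Total" else part.weeks == stratum
            if mask.sum() < 2:
                continue
            d = out["strata"].setdefault(str(stratum), {})
            d[split_name] = {
                "rmse": rmse(part.y[mask], pred[mask]),
                "r2": r2(part.y[mask], pred[mask]),
                "n": int(mask.sum()),
            }
        if split_name == "test":
            for yt, yp, pid, w in zip(part.y, pred, part.patient_ids, part.weeks):
                pred_rows.append({"patient_id": pid, "week": int(w),
                                  "y_true": float(yt), "y_pred": float(yp)})
    out["predictions"] = pd.DataFrame(pred_rows)
    return out


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Machine twin of the benchmark tables.

    ``table``: per (model, target, stratum, split) the fold mean +/- sd of
    RMSE and R^2.  ``scatter``: per-test-sample true vs predicted values.
    """

    table: pd.DataFrame
    scatter: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def to_text(self) -> str:
        lines = []
        for (model, target), grp in self.table.groupby(["model", "target"], sort=True):
            lines.append(f"== {model} / {target} ==")
            for row in grp.itertuples():
                lines.append(
                    f"  {row.stratum:>6} {row.split:<5} "
                    f"RMSE {row.rmse_mean:6.2f} ± {row.rmse_sd:5.2f}  "
                    f"R² {row.r2_mean:6.3f} ± {row.r2_sd:5.3f}  (n={row.n})"
                )
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out_dir / "report.csv", index=False)
        self.scatter.to_csv(out_dir / "scatter.csv", index=False)
        (out_dir / "report.txt").write_text(self.to_text() + "\n")


def _fold_partition(patients: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    patients = patients.copy()
    rng.shuffle(patients)
    return [patients[i::k] for i in range(k)]


def cross_validate(
    ds: SupervisedDataset,
    config: ModelConfig,
    spec: TrainSpec = TrainSpec(),
    k: int = 3,
    model_label: str | None = None,
) -> EvalReport:
    """Patient-level k-fold cross-validation (k=3 per the protocol).

    Patients are partitioned into k mutually exclusive subsets; each
    serves once as the test set while the others train (with the usual
    validation carve-out).  Metrics are aggregated as mean +/- sd over
    folds, per week stratum and overall.
    """
    spec.validate()
    if k < 2:
        raise ValueError("cross-validation requires k >= 2")
    patients = ds.patients
    if len(patients) < k:
        raise ValueError(f"need at least {k} patients for {k}-fold CV")
    folds = _fold_partition(patients, k, spec.seed)
    label = model_label or config.kind

    per_fold: dict[tuple, list] = {}
    scatter_rows = []
    for fold_i, test_p in enumerate(folds):
        train_p = np.concatenate([f for j, f in enumerate(folds) if j != fold_i])
        assert not set(train_p) & set(test_p), "patient leakage across folds"
        train_all = ds.subset_patients(train_p)
        test = ds.subset_patients(test_p)
        rng = np.random.default_rng(spec.seed + 17 * fold_i)
        tp = train_all.patients.copy()
        rng.shuffle(tp)
        n_val = max(1, int(round(spec.val_frac_of_train * len(tp))))
        val = train_all.subset_patients(tp[:n_val])
        train = train_all.subset_patients(tp[n_val:])

        handle = build_model(
            replace(config, seed=config.seed + fold_i),
            ds.X_ts.shape[1:], ds.X_static.shape[1],
            feature_dim=ds.X_flat.shape[1] - ds.X_static.shape[1],
        )
        train_model(handle, train, val, spec)

        for split_name, part in (("train", train), ("test", test)):
            pred = _predict_ds(handle, part)
            for stratum in [*TARGET_WEEKS[ds.target_name], "Total"]:
                mask = (np.ones(len(part), bool) if stratum == "Total"
                        else part.weeks == stratum)
                if mask.sum() < 2:
                    continue
                per_fold.setdefault((str(stratum), split_name), []).append(
                    (rmse(part.y[mask], pred[mask]), r2(part.y[mask], pred[mask]),
                     int(mask.sum()))
                )
            if split_name == "test":
                for yt, yp, pid, w in zip(part.y, pred, part.patient_ids, part.weeks):
                    scatter_rows.append(
                        {"model": label, "target": ds.target_name, "fold": fold_i,
                         "patient_id": pid, "week": int(w),
                         "y_true": float(yt), "y_pred": float(yp)}
                    )

    rows = []
    for (stratum, split_name), vals in per_fold.items():
        arr = np.array([(v[0], v[1]) for v in vals])
        rows.append(
            {"model": label, "target": ds.target_name, "stratum": stratum,
             "split": split_name, "rmse_mean": arr[:, 0].mean(),
             "rmse_sd": arr[:, 0].std(ddof=0), "r2_mean": arr[:, 1].mean(),
             "r2_sd": arr[:, 1].std(ddof=0), "n": sum(v[2] for v in vals),
             "n_folds": len(vals)}
        )
    return EvalReport(
        table=pd.DataFrame(rows),
        scatter=pd.DataFrame(scatter_rows),
        meta={"k": k, "seed": spec.seed, "config": config.__dict__.copy()},
    )


# ---------------------------------------------------------------------------
# Hyperparameter search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SearchSpace:
    """The protocol's hyperparameter grids."""

    dilations: tuple[int, ...] = (2, 4, 8, 16, 32)
    kernel_size: int = 3
    dropout_grid: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5)
    lstm_units_grid: tuple[int, ...] = (128, 256, 512)
    lr_min: float = 0.0001
    lr_max: float = 0.01
    lr_step: float = 0.0005
    fc_nodes: tuple[int, ...] = (128, 64, 32)
    n_random_draws: int = 20
    svr_c_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    svr_epsilon_grid: tuple[float, ...] = (0.01, 0.1, 0.5)

    @property
    def lr_grid(self) -> np.ndarray:
        return np.round(np.arange(self.lr_min, self.lr_max + 1e-12, self.lr_step), 6)

    def validate(self) -> None:
        for g in (self.dropout_grid, self.lstm_units_grid, self.svr_c_grid):
            if len(g) == 0:
                raise ValueError("empty search grid")
        if len(self.lr_grid) == 0:
            raise ValueError("empty learning-rate grid")


def _draw_config(space: SearchSpace, base: ModelConfig, rng) -> ModelConfig:
    if base.kind == "svr":
        return replace(
            base,
            svr_c=float(rng.choice(space.svr_c_grid)),
            svr_epsilon=float(rng.choice(space.svr_epsilon_grid)),
        )
    return replace(
        base,
        dilations=space.dilations,
        kernel_size=space.kernel_size,
        conv_dropout=float(rng.choice(space.dropout_grid)),
        lstm_dropout=float(rng.choice(space.dropout_grid)),
        lstm_units=int(rng.choice(space.lstm_units_grid)),
        learning_rate=float(rng.choice(space.lr_grid)),
        fc_nodes=space.fc_nodes,
    )


def _neighbours(grid, value):
    grid = sorted(grid)
    if value not in grid:
        return [value]
    i = grid.index(value)
    return sorted({grid[max(0, i - 1)], value, grid[min(len(grid) - 1, i + 1)]})


def hyperparameter_search(
    space: SearchSpace,
    ds: SupervisedDataset,
    spec: TrainSpec = TrainSpec(),
    budget: int = 20,
    base_config: ModelConfig = ModelConfig(),
) -> tuple[ModelConfig, pd.DataFrame]:
    """Random-search phase over the full space, then a local grid around
    the incumbent on the discrete axes; selection by validation loss.

    Returns (best config, leaderboard sorted by validation loss).
    """
    space.validate()
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(spec.seed)
    train, val, test = split_dataset(ds, spec)

    def evaluate(cfg: ModelConfig) -> float:
        handle = build_model(
            cfg, ds.X_ts.shape[1:], ds.X_static.shape[1],
            feature_dim=ds.X_flat.shape[1] - ds.X_static.shape[1],
        )
        train_model(handle, train, val, spec)
        if handle.is_neural:
            return handle.evaluate(val.X_ts, val.X_static, val.y)
        pred = handle.predict(flat=val.X_flat)
        return float(np.mean((pred.ravel() - val.y) ** 2))

    tried: dict = {}
    rows = []

    def consider(cfg: ModelConfig, phase: str):
        key = (cfg.conv_dropout, cfg.lstm_dropout, cfg.lstm_units,
               cfg.learning_rate, cfg.svr_c, cfg.svr_epsilon)
        if key in tried:
            return
        loss = evaluate(cfg)
        tried[key] = (loss, cfg)
        rows.append({"phase": phase, "val_loss": loss, **{
            "conv_dropout": cfg.conv_dropout, "lstm_dropout": cfg.lstm_dropout,
            "lstm_units": cfg.lstm_units, "learning_rate": cfg.learning_rate,
            "svr_c": cfg.svr_c, "svr_epsilon": cfg.svr_epsilon}})

    for _ in range(budget):
        consider(_draw_config(space, base_config, rng), "random")

    best_loss, best_cfg = min(tried.values(), key=lambda t: t[0])
    if base_config.kind == "svr":
        local = itertools.product(
            _neighbours(space.svr_c_grid, best_cfg.svr_c),
            _neighbours(space.svr_epsilon_grid, best_cfg.svr_epsilon),
        )
        for c, e in local:
            consider(replace(best_cfg, svr_c=c, svr_epsilon=e), "grid")
    else:
        local = itertools.product(
            _neighbours(space.dropout_grid, best_cfg.conv_dropout),
            _neighbours(space.lstm_units_grid, best_cfg.lstm_units),
            _neighbours(tuple(space.lr_grid), best_cfg.learning_rate),
        )
        for d, u, lr in local:
            consider(replace(best_cfg, conv_dropout=d, lstm_units=u, learning_rate=lr),
                     "grid")

    best_loss, best_cfg = min(tried.values(), key=lambda t: t[0])
    leaderboard = pd.DataFrame(rows).sort_values("val_loss").reset_index(drop=True)
    return best_cfg, leaderboard


# ---------------------------------------------------------------------------
# Benchmark harness
# ---------------------------------------------------------------------------


def benchmark_models(
    cohort: Cohort,
    configs: dict[str, ModelConfig] | None = None,
    spec: TrainSpec = TrainSpec(),
    targets: tuple[str, ...] = TARGET_NAMES,
    tensor_spec: TensorSpec = TensorSpec(),
    filter_spec: FilterSpec = FilterSpec(),
    k: int = 3,
) -> EvalReport:
    """Run the k-fold comparison of all model kinds over all targets.

    Produces the benchmark-table twin (RMSE / R^2 per model, target, week
    stratum and split) plus per-sample scatter data for the test folds.
    """
    if configs is None:
        configs = {kind: ModelConfig(kind=kind) for kind in
                   ("tcn_lstm", "tcn", "lstm", "svr")}
    tables, scatters = [], []
    for target in targets:
        ds = make_supervised_samples(cohort, target, tensor_spec, filter_spec)
        for kind, cfg in configs.items():
            rep = cross_validate(ds, cfg, spec, k=k, model_label=kind)
            tables.append(rep.table)
            scatters.append(rep.scatter)
    return EvalReport(
        table=pd.concat(tables, ignore_index=True),
        scatter=pd.concat(scatters, ignore_index=True),
        meta={"targets": list(targets), "k": k, "seed": spec.seed,
              "models": list(configs)},
    )
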