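"""Dataset assembly, splitting protocol, metrics, CV and search."""

import numpy as np
import pandas as pd
import pytest

from semgcobb import (
    ModelConfig,
    SearchSpace,
    SimParams,
    SupervisedDataset,
    TensorSpec,
    TrainSpec,
    benchmark_models,
    build_model,
    cross_validate,
    hyperparameter_search,
    make_supervised_samples,
    r2,
    rmse,
    simulate_cohort,
    split_dataset,
    train_model,
)
from semgcobb.train_eval import TARGET_NAMES, _fold_partition

MICRO_TENSOR = TensorSpec(target_rate_hz=25.0, target_len=50)
MICRO_MODEL = dict(
    dilations=(1, 2), kernel_size=2, n_filters=2, conv_dropout=0.1,
    lstm_units=4, n_lstm_layers=1, lstm_dropout=0.1, fc_nodes=(8,),
    static_nodes=(4,), tcn_pool=2, lstm_max_steps=25, seed=0,
)


@pytest.fixture(scope="module")
def micro_cobb_ds(micro_bench_cohort):
    return make_supervised_samples(micro_bench_cohort, "cobb_T", MICRO_TENSOR)


@pytest.fixture(scope="module")
def micro_bst_ds(micro_bench_cohort):
    return make_supervised_samples(micro_bench_cohort, "bst", MICRO_TENSOR)


class TestAssembly:
    def test_sample_counts(self, micro_cobb_ds, micro_bst_ds, micro_bench_cohort):
        n = len(micro_bench_cohort.statics)
        # Cobb: (patient, exercise) x radiographic weeks {0, 24}
        assert len(micro_cobb_ds) == n * 4 * 2
        assert set(micro_cobb_ds.weeks) == {0, 24}
        # endurance: all four measurement weeks
        assert len(micro_bst_ds) == n * 4 * 4
        for w in (0, 8, 16, 24):
            assert np.sum(micro_bst_ds.weeks == w) == n * 4

    def test_single_patient_counts(self):
        cohort, _ = simulate_cohort(SimParams(n_patients=1, duration_s=2.0, seed=2))
        assert len(make_supervised_samples(cohort, "bst", MICRO_TENSOR)) == 16
        assert len(make_supervised_samples(cohort, "cobb_T", MICRO_TENSOR)) == 8

    def test_unknown_target_rejected(self, micro_bench_cohort):
        with pytest.raises(ValueError, match="unknown target"):
            make_supervised_samples(micro_bench_cohort, "height", MICRO_TENSOR)

    def test_missing_label_raises(self, micro_bench_cohort):
        import copy

        broken = copy.copy(micro_bench_cohort)
        broken.outcomes = copy.deepcopy(micro_bench_cohort.outcomes)
        broken.outcomes[0].weeks[24].cobb_T = None
        with pytest.raises(ValueError, match="missing cobb_T label"):
            make_supervised_samples(broken, "cobb_T", MICRO_TENSOR)

    def test_flat_features_extend_static(self, micro_cobb_ds):
        assert micro_cobb_ds.X_flat.shape[1] == micro_cobb_ds.X_static.shape[1] + 8

    def test_pmsi_history_zero_after_sample_week(self, micro_bst_ds):
        from semgcobb.preprocess import _PMSI_OFFSET as OFF

        sv = micro_bst_ds.X_static
        w = micro_bst_ds.weeks
        # the PMSI block has 4 pairs x 4 weeks after [sex, sex, bmi, week]
        pmsi_block = sv[:, OFF:].reshape(len(sv), 4, 4)  # [n, week_slot, pair]
        for wi, week in enumerate((0, 8, 16, 24)):
            later = pmsi_block[w == week, wi + 1 :, :]
            assert np.all(later == 0)
            filled = pmsi_block[w == week, : wi + 1, :]
            assert np.all(np.any(filled != 0, axis=-1))


class TestSplit:
    def _fake_ds(self, n_patients, per=4):
        n = n_patients * per
        pid = np.repeat([f"P{i:04d}" for i in range(n_patients)], per)
        return SupervisedDataset(
            "cobb_T", np.zeros((n, 1, 4), np.float32), np.zeros((n, 2), np.float32),
            np.zeros((n, 3), np.float32), np.arange(n, dtype=float),
            pid, np.tile([0, 24], n // 2), np.array(["quadruped"] * n),
        )

    def test_seventy_thirty_patient_split(self):
        ds = self._fake_ds(143)
        train, val, test = split_dataset(ds, TrainSpec(seed=5))
        n_train = len(train.patients) + len(val.patients)
        assert n_train == 100  # floor(0.7 * 143)
        assert len(test.patients) == 43
        assert len(val.patients) == 10  # 10% of the training patients

    def test_no_patient_leakage(self):
        ds = self._fake_ds(20)
        train, val, test = split_dataset(ds, TrainSpec(seed=1))
        a, b, c = map(set, (train.patient_ids, val.patient_ids, test.patient_ids))
        assert not (a & b) and not (a & c) and not (b & c)
        assert a | b | c == set(ds.patient_ids)

    def test_split_deterministic(self):
        ds = self._fake_ds(12)
        s1 = split_dataset(ds, TrainSpec(seed=9))
        s2 = split_dataset(ds, TrainSpec(seed=9))
        for p1, p2 in zip(s1, s2):
            np.testing.assert_array_equal(p1.patient_ids, p2.patient_ids)

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError, match="at least 3 patients"):
            split_dataset(self._fake_ds(2), TrainSpec())

    def test_sample_level_split_option(self):
        ds = self._fake_ds(10)
        train, val, test = split_dataset(ds, TrainSpec(seed=2, group_by_patient=False))
        assert len(train) + len(val) + len(test) == len(ds)


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 5.0])
        assert rmse(y, y) == 0.0
        assert r2(y, y) == 1.0

    def test_mean_prediction_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0])
        yhat = np.full(3, y.mean())
        assert r2(y, yhat) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        y = np.array([1.0, 2.0, 3.0])
        yhat = np.array([2.0, 2.0, 2.0])
        assert rmse(y, yhat) == pytest.approx(np.sqrt(2.0 / 3.0), rel=1e-12)
        assert r2(y, yhat) == pytest.approx(0.0, abs=1e-12)

    def test_identity_links_rmse_and_r2(self, rng):
        y = rng.normal(size=50)
        yhat = y + rng.normal(scale=0.5, size=50)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert r2(y, yhat) == pytest.approx(
            1.0 - rmse(y, yhat) ** 2 * len(y) / ss_tot, rel=1e-9
        )

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import mean_squared_error, r2_score

        y = rng.normal(size=30)
        yhat = rng.normal(size=30)
        assert rmse(y, yhat) == pytest.approx(np.sqrt(mean_squared_error(y, yhat)))
        assert r2(y, yhat) == pytest.approx(r2_score(y, yhat))

    def test_error_conditions(self):
        with pytest.raises(ValueError):
            rmse(np.array([1.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="constant"):
            r2(np.array([2.0, 2.0]), np.array([1.0, 2.0]))


class TestTraining:
    def test_early_stopping_on_plateau(self, micro_cobb_ds):
        # lr = 0: the validation loss is frozen from epoch 1, so training
        # halts at epoch patience + 1 with the first epoch kept as best
        cfg = ModelConfig(kind="tcn_lstm", learning_rate=0.0, **MICRO_MODEL)
        h = build_model(cfg, micro_cobb_ds.X_ts.shape[1:], micro_cobb_ds.X_static.shape[1])
        train, val, _ = split_dataset(micro_cobb_ds, TrainSpec(seed=1))
        hist = train_model(h, train, val, TrainSpec(max_epochs=100, patience=10, seed=1))
        assert hist["stopped_epoch"] == 11
        assert hist["best_epoch"] == 1

    def test_history_bounded_by_max_epochs(self, micro_cobb_ds):
        cfg = ModelConfig(kind="tcn_lstm", learning_rate=0.005, **MICRO_MODEL)
        h = build_model(cfg, micro_cobb_ds.X_ts.shape[1:], micro_cobb_ds.X_static.shape[1])
        train, val, _ = split_dataset(micro_cobb_ds, TrainSpec(seed=1))
        hist = train_model(h, train, val, TrainSpec(max_epochs=4, patience=4, seed=1))
        assert len(hist["val_loss"]) <= 4
        # running minimum of the validation loss is non-increasing
        run_min = np.minimum.accumulate(hist["val_loss"])
        assert np.all(np.diff(run_min) <= 0)

    def test_restores_best_weights(self, micro_cobb_ds):
        cfg = ModelConfig(kind="tcn_lstm", learning_rate=0.01, **MICRO_MODEL)
        h = build_model(cfg, micro_cobb_ds.X_ts.shape[1:], micro_cobb_ds.X_static.shape[1])
        train, val, _ = split_dataset(micro_cobb_ds, TrainSpec(seed=1))
        hist = train_model(h, train, val, TrainSpec(max_epochs=6, patience=6, seed=1))
        best = min(hist["val_loss"])
        final = h.evaluate(val.X_ts, val.X_static, val.y)
        assert final == pytest.approx(best, rel=1e-5)


class TestCrossValidation:
    def test_folds_partition_patients_exactly(self):
        patients = np.array([f"P{i:03d}" for i in range(17)])
        folds = _fold_partition(patients, 3, seed=4)
        assert sorted(np.concatenate(folds)) == sorted(patients)
        assert sum(len(f) for f in folds) == 17
        flat = set()
        for f in folds:
            assert not flat & set(f)
            flat |= set(f)

    def test_report_strata_and_test_coverage(self, micro_cobb_ds, micro_bst_ds):
        cfg = ModelConfig(kind="svr", svr_c=1.0)
        rep = cross_validate(micro_cobb_ds, cfg, TrainSpec(seed=3), k=3)
        strata = set(rep.table[rep.table.split == "test"].stratum)
        assert strata == {"0", "24", "Total"}
        # every sample lands in a test fold exactly once
        counts = rep.scatter.groupby(["patient_id", "week"]).size()
        assert (counts == 4).all()  # 4 exercises per (patient, week)
        assert len(rep.scatter) == len(micro_cobb_ds)
        rep_bst = cross_validate(micro_bst_ds, cfg, TrainSpec(seed=3), k=3)
        assert set(rep_bst.table[rep_bst.table.split == "test"].stratum) == {
            "0", "8", "16", "24", "Total"}

    def test_k_below_two_rejected(self, micro_cobb_ds):
        with pytest.raises(ValueError, match="k >= 2"):
            cross_validate(micro_cobb_ds, ModelConfig(kind="svr"), TrainSpec(), k=1)


class TestSearch:
    def test_singleton_space_returned(self, micro_cobb_ds):
        space = SearchSpace(dropout_grid=(0.1,), lstm_units_grid=(4,),
                            lr_min=0.001, lr_max=0.001, lr_step=0.0005,
                            svr_c_grid=(1.0,), svr_epsilon_grid=(0.1,))
        base = ModelConfig(kind="svr")
        best, board = hyperparameter_search(space, micro_cobb_ds, TrainSpec(seed=1),
                                            budget=1, base_config=base)
        assert best.svr_c == 1.0 and best.svr_epsilon == 0.1
        assert len(board) == 1

    def test_leaderboard_sorted_and_planted_optimum(self, micro_bench_cohort):
        # planted optimum: a drastically under-regularised SVR (C = 1e-6)
        # cannot fit the Cobb signal; C = 10 strictly dominates.  The
        # exhaustive-evaluation oracle over this 2-point space is the
        # search itself at full budget.
        ds = make_supervised_samples(micro_bench_cohort, "cobb_T", MICRO_TENSOR)
        space = SearchSpace(svr_c_grid=(1e-6, 10.0), svr_epsilon_grid=(0.1,))
        best, board = hyperparameter_search(
            space, ds, TrainSpec(seed=2), budget=10, base_config=ModelConfig(kind="svr")
        )
        assert best.svr_c == 10.0
        assert board.val_loss.is_monotonic_increasing

    def test_neural_search_smoke(self, micro_cobb_ds):
        space = SearchSpace(dilations=(1, 2), kernel_size=2,
                            dropout_grid=(0.1, 0.3), lstm_units_grid=(4,),
                            lr_min=0.001, lr_max=0.002, lr_step=0.001)
        base = ModelConfig(kind="tcn_lstm", **MICRO_MODEL)
        best, board = hyperparameter_search(
            space, micro_cobb_ds, TrainSpec(seed=3, max_epochs=2, patience=2),
            budget=2, base_config=base,
        )
        assert best.lstm_units == 4
        assert (board.phase == "grid").any()


def test_benchmark_report_structure(micro_bench_cohort):
    """The report twin: 4 model kinds x 6 targets x week strata x splits."""
    configs = {k: ModelConfig(kind=k, **MICRO_MODEL) for k in ("tcn_lstm", "tcn", "lstm")}
    configs["svr"] = ModelConfig(kind="svr")
    rep = benchmark_models(
        micro_bench_cohort, configs, TrainSpec(seed=1, max_epochs=1, patience=1),
        targets=TARGET_NAMES, tensor_spec=MICRO_TENSOR, k=2,
    )
    t = rep.table
    assert set(t.model) == {"tcn_lstm", "tcn", "lstm", "svr"}
    assert set(t.target) == set(TARGET_NAMES)
    for target in TARGET_NAMES:
        strata = set(t[(t.target == target) & (t.split == "test")].stratum)
        expect = {"0", "24", "Total"} if target.startswith("cobb") else {
            "0", "8", "16", "24", "Total"}
        assert strata == expect, target
    assert set(t.split) == {"train", "test"}
    assert (t.rmse_mean >= 0).all()
    assert (t.r2_mean <= 1.0).all()
    assert {"model", "target", "fold", "week", "y_true", "y_pred"} <= set(rep.scatter.columns)
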