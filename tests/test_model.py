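"""Model construction, training contracts, cross-validation folds,
hyperparameter selection, and the precision = recall threshold rule."""

import numpy as np
import pytest

from vapwarn.model import (
    DecisionThreshold,
    ModelConfig,
    build_model,
    cross_validate,
    lstm_param_count,
    select_threshold,
    train,
    tune_hyperparameters,
)

TINY = ModelConfig(
    n_recurrent_layers=1, cells_per_layer=8, batch_size=32, max_epochs=30,
    patience=10, seed=0,
)


def separable_sequences(n, seed=0, signal=3.0, t_steps=12, features=3):
    """Positives carry a rising ramp in feature 0 over the last steps."""
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.5).astype(int)
    X = rng.standard_normal((n, t_steps, features)) * 0.5
    ramp = np.linspace(0, signal, t_steps)
    X[y == 1, :, 0] += ramp
    return X.astype(np.float32), y


class TestBuildModel:
    def test_forward_output_in_unit_interval(self):
        m = build_model(ModelConfig(seed=1))
        x = np.random.default_rng(0).standard_normal((1, 24, 5))
        p = m.predict_proba(x)
        assert 0.0 < p[0] < 1.0

    def test_same_seed_identical_initial_params(self):
        a = build_model(ModelConfig(seed=4))
        b = build_model(ModelConfig(seed=4))
        for k in a.net.params:
            assert np.array_equal(a.net.params[k], b.net.params[k])

    def test_param_count_matches_hand_formula(self):
        """Independent arithmetic: each LSTM layer has 4*(d*H + H*H + H)
        weights (d = input size), plus the H+1 read-out."""
        for layers, hidden in [(3, 50), (1, 8), (2, 16)]:
            m = build_model(
                ModelConfig(n_recurrent_layers=layers, cells_per_layer=hidden)
            )
            expected, d = 0, 5
            for _ in range(layers):
                expected += 4 * (d * hidden + hidden * hidden + hidden)
                d = hidden
            expected += hidden + 1
            assert m.n_params == expected
            assert lstm_param_count(5, layers, hidden) == expected

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(dropout_rate=0.7)
        with pytest.raises(ValueError):
            ModelConfig(cells_per_layer=0)


class TestTrain:
    def test_converges_on_separable_data(self):
        X, y = separable_sequences(400, seed=1)
        Xv, yv = separable_sequences(200, seed=2)
        cfg = ModelConfig(
            n_recurrent_layers=1, cells_per_layer=8, batch_size=32,
            max_epochs=60, patience=60, learning_rate=3e-3, seed=0,
        )
        m = build_model(cfg, n_features=3)
        m = train(m, (X, y), (Xv, yv), cfg)
        assert min(m.history["train_loss"]) < 0.1
        assert m.history["best_val_auprc"] > 0.95

    def test_permuted_labels_give_chance_auprc(self):
        X, y = separable_sequences(400, seed=3)
        rng = np.random.default_rng(4)
        y_perm = rng.permutation(y)
        Xv, yv = separable_sequences(200, seed=5)
        yv_perm = rng.permutation(yv)
        cfg = ModelConfig(
            n_recurrent_layers=1, cells_per_layer=8, batch_size=32,
            max_epochs=10, patience=3, seed=0,
        )
        m = build_model(cfg, n_features=3)
        m = train(m, (X, y_perm), (Xv, yv_perm), cfg)
        prevalence = yv_perm.mean()
        assert abs(m.history["best_val_auprc"] - prevalence) < 0.15

    def test_same_seed_identical_history(self):
        X, y = separable_sequences(200, seed=6)
        Xv, yv = separable_sequences(100, seed=7)
        cfg = ModelConfig(
            n_recurrent_layers=1, cells_per_layer=6, batch_size=32,
            max_epochs=5, patience=5, seed=11,
        )
        hists = []
        for _ in range(2):
            m = build_model(cfg, n_features=3)
            m = train(m, (X, y), (Xv, yv), cfg)
            hists.append(m.history)
        assert hists[0]["train_loss"] == hists[1]["train_loss"]
        assert hists[0]["val_auprc"] == hists[1]["val_auprc"]

    def test_validation_without_positives_rejected(self):
        X, y = separable_sequences(50, seed=8)
        m = build_model(TINY, n_features=3)
        with pytest.raises(ValueError, match="positive"):
            train(m, (X, y), (X, np.zeros(len(X), dtype=int)), TINY)


def stub_train_fn(Xtr, ytr, Xval, yval, config, fold):
    """Scores = feature-0 mean of the last timestep (no training), enough
    to exercise fold bookkeeping deterministically."""
    return Xval[:, -1, 0]


class TestCrossValidate:
    def _data(self, n_groups=10, per_group=8, seed=0):
        rng = np.random.default_rng(seed)
        X, y, g = [], [], []
        for i in range(n_groups):
            pos_group = i % 2 == 0
            for j in range(per_group):
                x = rng.standard_normal((12, 3))
                label = int(pos_group and j < 2)
                x[:, 0] += 2 * label
                X.append(x)
                y.append(label)
                g.append(f"G{i}")
        return np.array(X), np.array(y), np.array(g)

    def test_each_fold_holds_two_of_ten_groups(self):
        X, y, g = self._data()
        res = cross_validate(X, y, g, TINY, n_folds=5, train_fn=stub_train_fn)
        for fold_idx in res["folds"]:
            assert len({g[i] for i in fold_idx}) == 2

    def test_folds_partition_dataset(self):
        X, y, g = self._data()
        res = cross_validate(X, y, g, TINY, n_folds=5, train_fn=stub_train_fn)
        all_idx = np.concatenate(res["folds"])
        assert sorted(all_idx.tolist()) == list(range(len(X)))

    def test_fold_positive_fractions_balanced_across_seeds(self):
        X, y, g = self._data(n_groups=20, per_group=10)
        global_frac = y.mean()
        for seed in range(20):
            cfg = ModelConfig(
                n_recurrent_layers=1, cells_per_layer=4, seed=seed
            )
            res = cross_validate(X, y, g, cfg, n_folds=5, train_fn=stub_train_fn)
            for fold_idx in res["folds"]:
                frac = y[fold_idx].mean()
                assert abs(frac - global_frac) / global_frac <= 0.2

    def test_too_few_positive_groups_rejected(self):
        X, y, g = self._data(n_groups=4)
        with pytest.raises(ValueError, match="positive groups"):
            cross_validate(X, y, g, TINY, n_folds=5, train_fn=stub_train_fn)


class TestTuneHyperparameters:
    def test_single_config_returned(self):
        cfg = ModelConfig(seed=1)
        best, board = tune_hyperparameters([cfg], None, None, scorer=lambda c: 0.5)
        assert best == cfg and len(board) == 1

    def test_stubbed_scorer_matches_argmax(self):
        space = [
            ModelConfig(cells_per_layer=c, dropout_rate=d, seed=0)
            for c in (10, 20) for d in (0.05, 0.10)
        ]
        values = {(c.cells_per_layer, c.dropout_rate): v
                  for c, v in zip(space, (0.4, 0.9, 0.7, 0.2))}
        best, board = tune_hyperparameters(
            space, None, None,
            scorer=lambda c: values[(c.cells_per_layer, c.dropout_rate)],
        )
        assert values[(best.cells_per_layer, best.dropout_rate)] == 0.9
        assert [r["val_auprc"] for r in board] == sorted(
            values.values(), reverse=True
        )

    def test_ties_break_to_fewer_params_then_lower_dropout(self):
        space = [
            ModelConfig(cells_per_layer=20, dropout_rate=0.10, seed=0),
            ModelConfig(cells_per_layer=10, dropout_rate=0.10, seed=0),
            ModelConfig(cells_per_layer=10, dropout_rate=0.05, seed=0),
        ]
        best, _ = tune_hyperparameters(space, None, None, scorer=lambda c: 0.8)
        assert best.cells_per_layer == 10 and best.dropout_rate == 0.05

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError):
            tune_hyperparameters([], None, None)


def oracle_threshold(scores, labels):
    best = None
    n_pos = labels.sum()
    for t in np.unique(scores):
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        if tp + fp == 0:
            continue
        precision, recall = tp / (tp + fp), tp / n_pos
        key = (abs(precision - recall), -recall, t)
        if best is None or key < best:
            best = key
    return best


class TestSelectThreshold:
    def test_separable_two_point_case(self):
        thr = select_threshold(np.array([0.9, 0.1]), np.array([1, 0]))
        assert thr.threshold == pytest.approx(0.9)
        assert thr.precision_at_threshold == 1.0
        assert thr.recall_at_threshold == 1.0

    def test_all_scores_equal_degenerate(self):
        labels = np.array([1, 0, 0, 1, 0])
        thr = select_threshold(np.full(5, 0.5), labels)
        assert thr.recall_at_threshold == 1.0
        assert thr.precision_at_threshold == pytest.approx(labels.mean())

    def test_matches_exhaustive_scan_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n = int(rng.integers(5, 60))
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.random(n), 2)
            thr = select_threshold(scores, labels)
            key = oracle_threshold(scores, labels)
            assert abs(
                thr.precision_at_threshold - thr.recall_at_threshold
            ) == pytest.approx(key[0])
            assert thr.threshold == pytest.approx(key[2])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            select_threshold(np.array([0.3, 0.4]), np.array([1, 1]))
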