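"""The VAP sequence classifier: stacked-LSTM training, stratified group
cross-validation, hyperparameter search on validation AUPRC, and
precision = recall threshold selection.

The default architecture is 3 LSTM layers of 50 cells with a sigmoid
read-out; training minimizes binary cross-entropy with Adam and stops
early on validation AUPRC.  One model is trained per prediction horizon,
since the labels differ per horizon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from ._common import rng_from_seed
from .nn import Adam, DTYPE, LSTMNet, bce_loss

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelConfig:
    n_recurrent_layers: int = 3
    cells_per_layer: int = 50
    dropout_rate: float = 0.10
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0
    #: fixed shrinkage of z-scored inputs before the first recurrent layer;
    #: keeps multi-sigma excursions inside the gates' responsive range
    input_scale: float = 1.0 / 3.0
    #: L2 penalty on weight matrices (not biases). The SMOTE-balanced
    #: training set is nearly separable, so unpenalized training fits it in
    #: an epoch or two and stops refining; decay keeps gradients alive
    weight_decay: float = 3e-3

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_rate <= 0.5):
            raise ValueError(f"dropout_rate {self.dropout_rate} outside [0, 0.5]")
        for name in ("n_recurrent_layers", "cells_per_layer", "batch_size",
                     "max_epochs", "patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")


@dataclass
class FittedModel:
    net: LSTMNet
    config: ModelConfig
    history: dict = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return self.net.n_params

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(np.asarray(X))

    def input_gradients(self, X: np.ndarray) -> np.ndarray:
        return self.net.input_gradients(np.asarray(X))


@dataclass(frozen=True)
class DecisionThreshold:
    horizon_hours: int
    threshold: float
    precision_at_threshold: float
    recall_at_threshold: float


def lstm_param_count(n_features: int, n_layers: int, hidden: int) -> int:
    """Closed-form parameter count of the stacked architecture."""
    total = 0
    d = n_features
    for _ in range(n_layers):
        total += 4 * hidden * (d + hidden + 1)
        d = hidden
    total += hidden + 1  # read-out
    return total


def build_model(config: ModelConfig, n_features: int = 5) -> FittedModel:
    """An untrained model; identical config and seed give identical
    initial parameters."""
    net = LSTMNet(
        n_features=n_features,
        n_layers=config.n_recurrent_layers,
        hidden=config.cells_per_layer,
        dropout=config.dropout_rate,
        seed=config.seed,
        input_scale=config.input_scale,
    )
    logger.info("built LSTM with %d parameters", net.n_params)
    return FittedModel(net=net, config=config, history={})


def train(
    model: FittedModel,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    config: ModelConfig | None = None,
) -> FittedModel:
    """Minimize BCE with Adam; early-stop on validation AUPRC.

    ``train_data`` should already be class-balanced (SMOTE) and normalized;
    ``val_data`` must be untouched by SMOTE.  Best-epoch parameters are
    restored before returning.
    """
    config = config or model.config
    Xtr, ytr = np.asarray(train_data[0], dtype=DTYPE), np.asarray(train_data[1])
    Xval, yval = np.asarray(val_data[0], dtype=DTYPE), np.asarray(val_data[1])
    if yval.sum() == 0:
        raise ValueError("validation set has no positive labels: AUPRC undefined")

    rng = rng_from_seed(config.seed)
    opt = Adam(model.net.params, lr=config.learning_rate)
    history = {"train_loss": [], "val_auprc": []}
    best_state, best_auprc, best_epoch, since_best = None, -np.inf, -1, 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(Xtr))
        losses = []
        for s in range(0, len(order), config.batch_size):
            idx = order[s : s + config.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            prob, cache = model.net.forward(xb, training=True, rng=rng)
            losses.append(bce_loss(prob, yb) * len(idx))
            eps = 1e-7
            p = np.clip(prob, eps, 1.0 - eps)
            # d BCE / d p, averaged over the batch
            dprob = ((p - yb) / (p * (1.0 - p))) / len(idx)
            grads, _ = model.net.backward(cache, dprob.astype(DTYPE))
            if config.weight_decay > 0:
                for k, param in model.net.params.items():
                    if not k.startswith("b"):  # decay weights, not biases
                        grads[k] = grads[k] + DTYPE(config.weight_decay) * param
            opt.step(model.net.params, grads)
        val_scores = model.net.predict_proba(Xval)
        val_auprc = float(average_precision_score(yval, val_scores))
        history["train_loss"].append(float(np.sum(losses) / len(Xtr)))
        history["val_auprc"].append(val_auprc)
        if val_auprc > best_auprc:
            best_auprc, best_epoch, since_best = val_auprc, epoch, 0
            best_state = model.net.get_state()
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if best_state is not None:
        model.net.set_state(best_state)
    history["best_epoch"] = best_epoch
    history["best_val_auprc"] = best_auprc
    model.history = history
    return model


def _stratified_group_folds(
    groups: np.ndarray, group_positive: dict, n_folds: int, seed: int,
    group_sizes: dict | None = None,
) -> list[np.ndarray]:
    """Assign groups to folds balancing fold sizes and positive content.

    Positive groups (descending window count) go greedily to the fold with
    the least positive mass, then negative groups fill up the smallest
    folds; seeded shuffles break ties.  Returns per-sample fold ids.
    """
    uniq = sorted(set(groups.tolist()))
    sizes = group_sizes or {g: int((groups == g).sum()) for g in uniq}
    rng = rng_from_seed(seed)
    pos = [g for g in uniq if group_positive[g]]
    neg = [g for g in uniq if not group_positive[g]]
    pos = [pos[i] for i in rng.permutation(len(pos))]
    neg = [neg[i] for i in rng.permutation(len(neg))]
    pos.sort(key=lambda g: -sizes[g])
    neg.sort(key=lambda g: -sizes[g])

    n_groups = len(uniq)
    cap = [n_groups // n_folds + (1 if k < n_groups % n_folds else 0)
           for k in range(n_folds)]
    count = [0] * n_folds
    pos_mass = [0] * n_folds
    total_mass = [0] * n_folds
    assign: dict = {}
    for g in pos:
        k = min(
            (k for k in range(n_folds) if count[k] < cap[k]),
            key=lambda k: (pos_mass[k], count[k]),
        )
        assign[g] = k
        count[k] += 1
        pos_mass[k] += sizes[g]
        total_mass[k] += sizes[g]
    for g in neg:
        k = min(
            (k for k in range(n_folds) if count[k] < cap[k]),
            key=lambda k: (total_mass[k], count[k]),
        )
        assign[g] = k
        count[k] += 1
        total_mass[k] += sizes[g]
    fold_of = np.array([assign[g] for g in groups])
    return [np.where(fold_of == k)[0] for k in range(n_folds)]


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    config: ModelConfig,
    n_folds: int = 5,
    train_fn=None,
) -> dict:
    """Group-aware stratified k-fold: per-fold AUPRC/AUROC, mean and sd.

    ``train_fn(Xtr, ytr, Xval, yval, config, fold) -> scores`` may be
    injected (testing, baselines); default trains the LSTM.
    """
    groups = np.asarray(groups)
    uniq = sorted(set(groups.tolist()))
    group_pos = {g: bool(y[groups == g].sum()) for g in uniq}
    n_pos_groups = sum(group_pos.values())
    if n_pos_groups < n_folds:
        raise ValueError(
            f"{n_pos_groups} positive groups cannot stratify {n_folds} folds"
        )
    folds = _stratified_group_folds(groups, group_pos, n_folds, config.seed)

    per_fold = {"auprc": [], "auroc": []}
    for k, val_idx in enumerate(folds):
        tr_idx = np.concatenate([f for j, f in enumerate(folds) if j != k])
        if train_fn is None:
            m = build_model(config, n_features=X.shape[-1])
            m = train(m, (X[tr_idx], y[tr_idx]), (X[val_idx], y[val_idx]), config)
            scores = m.predict_proba(X[val_idx])
        else:
            scores = train_fn(X[tr_idx], y[tr_idx], X[val_idx], y[val_idx], config, k)
        per_fold["auprc"].append(float(average_precision_score(y[val_idx], scores)))
        per_fold["auroc"].append(float(roc_auc_score(y[val_idx], scores)))
    return {
        "folds": folds,
        "auprc": per_fold["auprc"],
        "auroc": per_fold["auroc"],
        "auprc_mean": float(np.mean(per_fold["auprc"])),
        "auprc_sd": float(np.std(per_fold["auprc"], ddof=1)),
        "auroc_mean": float(np.mean(per_fold["auroc"])),
        "auroc_sd": float(np.std(per_fold["auroc"], ddof=1)),
    }


def tune_hyperparameters(
    search_space: list[ModelConfig],
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    scorer=None,
) -> tuple[ModelConfig, list[dict]]:
    """Grid search maximizing validation AUPRC.

    Ties break toward fewer parameters, then lower dropout.  Returns the
    best config and the full leaderboard (descending AUPRC).  ``scorer``
    may be injected: ``scorer(config) -> val_auprc``.
    """
    if not search_space:
        raise ValueError("empty hyperparameter search space")

    def default_scorer(config: ModelConfig) -> float:
        m = build_model(config, n_features=np.asarray(train_data[0]).shape[-1])
        m = train(m, train_data, val_data, config)
        return float(m.history["best_val_auprc"])

    scorer = scorer or default_scorer
    rows = []
    for config in search_space:
        auprc = float(scorer(config))
        n_par = lstm_param_count(5, config.n_recurrent_layers, config.cells_per_layer)
        rows.append({"config": config, "val_auprc": auprc, "n_params": n_par})
    rows.sort(key=lambda r: (-r["val_auprc"], r["n_params"], r["config"].dropout_rate))
    for r in rows:
        logger.info("HPO %s -> AUPRC %.4f", asdict(r["config"]), r["val_auprc"])
    return rows[0]["config"], rows


def select_threshold(
    scores: np.ndarray, labels: np.ndarray, horizon_hours: int = 0
) -> DecisionThreshold:
    """The operating point where precision equals recall (sensitivity = PPV).

    Scans every unique score as a candidate threshold (prediction rule:
    score >= threshold is positive) and returns the one minimizing
    |precision - recall|; ties break toward higher recall, then toward the
    lower (more sensitive) threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("threshold selection needs both classes present")

    best = None
    for t in np.unique(scores):
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        if tp + fp == 0:
            continue
        precision = tp / (tp + fp)
        recall = tp / n_pos
        key = (abs(precision - recall), -recall, t)
        if best is None or key < best[0]:
            best = (key, float(t), precision, recall)
    assert best is not None
    return DecisionThreshold(horizon_hours, best[1], best[2], best[3])
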