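"""Baseline classifiers — random forest, gradient-boosted trees, logistic
regression — trained on the identical windowed dataset.

Non-sequential learners receive each 24x5 window flattened row-major by
hour into a 120-vector (feature 0 is hour-0 respiratory rate, feature 119
is hour-23 SpO2); the flattening is a bijection, so the comparison
isolates the learner, not the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from xgboost import XGBClassifier

from ._common import N_VITALS, WINDOW_HOURS

BASELINE_KINDS = ("random_forest", "gradient_boosting", "logistic_regression")


def featurize(values: np.ndarray) -> np.ndarray:
    """Row-major flattening of ``(..., 24, 5)`` windows to ``(..., 120)``."""
    values = np.asarray(values)
    return values.reshape(values.shape[:-2] + (WINDOW_HOURS * N_VITALS,))


def unflatten(features: np.ndarray) -> np.ndarray:
    features = np.asarray(features)
    return features.reshape(features.shape[:-1] + (WINDOW_HOURS, N_VITALS))


def feature_name(index: int) -> str:
    from ._common import VITALS

    return f"h{index // N_VITALS:02d}_{VITALS[index % N_VITALS]}"


@dataclass
class FittedBaseline:
    kind: str
    estimator: object
    seed: int

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        flat = featurize(X) if np.asarray(X).ndim == 3 else np.asarray(X)
        return self.estimator.predict_proba(flat)[:, 1]


def train_baseline(
    kind: str,
    train_data: tuple[np.ndarray, np.ndarray],
    seed: int = 0,
    n_estimators: int = 500,
) -> FittedBaseline:
    """Fit one baseline on (SMOTE-balanced) flattened training windows.

    Hyperparameters are library defaults apart from the tree count (500,
    for stability of the ensembles) and fixed seeds.
    """
    X, y = train_data
    flat = featurize(X) if np.asarray(X).ndim == 3 else np.asarray(X)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("baseline training requires both classes")

    if kind == "random_forest":
        est = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed, n_jobs=1
        )
    elif kind == "gradient_boosting":
        est = XGBClassifier(
            n_estimators=n_estimators,
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
            verbosity=0,
        )
    elif kind == "logistic_regression":
        est = LogisticRegression(max_iter=2000, random_state=seed)
    else:
        raise ValueError(f"unknown baseline kind {kind!r}")
    est.fit(flat, y)
    return FittedBaseline(kind=kind, estimator=est, seed=seed)
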