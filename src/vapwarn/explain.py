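"""Integrated-gradients attribution over the 24x5 input windows.

For a differentiable scorer f and baseline b, the attribution of input
cell i is ``(x_i - b_i)`` times the path-averaged partial derivative of f
along the straight line from b to x, approximated with a midpoint Riemann
sum.  The completeness axiom — attributions sum to f(x) - f(b) — is
reported as a gap and shrinks as the number of steps grows.  The default
baseline is all-zeros in normalized space, i.e. the per-variable training
mean in raw units: attributions measure the effect of deviating from an
average patient-hour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._common import VITALS


@dataclass
class AttributionMap:
    attributions: np.ndarray   # (24, 5)
    baseline: np.ndarray       # (24, 5)
    n_steps: int
    completeness_gap: float
    f_input: float
    f_baseline: float


@dataclass
class FeatureImportance:
    values: dict[str, float]
    rule: str


class LinearSurrogate:
    """f(x) = w . x + c — IG has the closed form (x - b) * w at any step
    count; used to validate the attribution machinery."""

    def __init__(self, weights: np.ndarray, intercept: float = 0.0):
        self.weights = np.asarray(weights, dtype=float)
        self.intercept = float(intercept)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X * self.weights).sum(axis=(1, 2)) + self.intercept

    def input_gradients(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.broadcast_to(self.weights, X.shape).copy()


def integrated_gradients(
    model, window: np.ndarray, baseline: np.ndarray | None = None, n_steps: int = 50
) -> AttributionMap:
    """Midpoint-rule integrated gradients for one window.

    ``model`` must expose ``predict_proba`` and ``input_gradients`` over
    batches shaped ``(n, 24, 5)`` (the fitted LSTM and
    :class:`LinearSurrogate` both do).
    """
    x = np.asarray(window, dtype=float)
    b = np.zeros_like(x) if baseline is None else np.asarray(baseline, dtype=float)
    if b.shape != x.shape:
        raise ValueError("baseline must have the window's shape")
    alphas = (np.arange(n_steps) + 0.5) / n_steps
    points = b[None] + alphas[:, None, None] * (x - b)[None]
    grads = np.asarray(model.input_gradients(points))
    if not np.isfinite(grads).all():
        raise FloatingPointError("non-finite gradients along the IG path")
    avg_grad = grads.mean(axis=0)
    attributions = (x - b) * avg_grad
    f_x = float(np.asarray(model.predict_proba(x[None]))[0])
    f_b = float(np.asarray(model.predict_proba(b[None]))[0])
    gap = abs(float(attributions.sum()) - (f_x - f_b))
    return AttributionMap(
        attributions=attributions,
        baseline=b,
        n_steps=n_steps,
        completeness_gap=gap,
        f_input=f_x,
        f_baseline=f_b,
    )


def aggregate_importance(
    maps: list[AttributionMap], rule: str = "mean_abs"
) -> FeatureImportance:
    """Per-variable scalar importance over a window collection.

    ``mean_abs`` (default): mean over windows and timesteps of the absolute
    attribution — non-negative.  ``signed_mean``: plain mean, sign kept.
    """
    if not maps:
        raise ValueError("no attribution maps to aggregate")
    stack = np.stack([m.attributions for m in maps])  # (n, 24, 5)
    if rule == "mean_abs":
        per_var = np.abs(stack).mean(axis=(0, 1))
    elif rule == "signed_mean":
        per_var = stack.mean(axis=(0, 1))
    else:
        raise ValueError(f"unknown aggregation rule {rule!r}")
    return FeatureImportance(
        values={v: float(per_var[j]) for j, v in enumerate(VITALS)}, rule=rule
    )


def attribution_trace(map_: AttributionMap) -> dict[str, np.ndarray]:
    """Per-timestep attribution trace per vital (the window-scale view)."""
    return {v: map_.attributions[:, j].copy() for j, v in enumerate(VITALS)}
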