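"""Hourly gridding, interpolation, normalization, sliding windows, SMOTE
and stratified splitting.

The model input is a 24 h observation window of hourly vital signs (a 24x5
matrix, column order ``_common.VITALS``) sliding forward 1 h at a time.  A
window is emitted when its end lies inside the episode's VAP risk period,
and it is labelled positive for a prediction horizon of h hours when a VAP
onset falls in the half-open interval (obs_end, obs_end + h] — e.g. an
onset 4 h past the window end is positive at the 6 h horizon.  Windows
whose observation reaches an onset or overlaps the 48 h of active infection
after it are censored: a window that already observes the infection is
neither a usable negative nor a prediction task.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from ._common import (
    EVENT_MERGE_GAP,
    HOUR,
    N_VITALS,
    VITALS,
    WINDOW_HOURS,
    rng_from_seed,
)
from .episodes import MVEpisode, RiskPeriod

logger = logging.getLogger(__name__)


class EpisodeExclusionError(ValueError):
    """Raised when an episode lacks the vital-sign coverage required for
    gridding (mirrors the complete-records inclusion criterion)."""


@dataclass
class HourlyGrid:
    episode_id: str
    t0: int                 # minutes; grid hour h covers [t0+60h, t0+60(h+1))
    matrix: np.ndarray      # (n_hours, 5) float
    imputed_mask: np.ndarray  # (n_hours, 5) bool, True where cell was empty


@dataclass(frozen=True)
class NormalizationStats:
    mean: np.ndarray  # (5,)
    sd: np.ndarray    # (5,)


@dataclass
class TemporalWindow:
    episode_id: str
    obs_start: int
    obs_end: int
    values: np.ndarray            # (24, 5)
    labels: dict[int, int]        # horizon hours -> {0, 1}


@dataclass
class SplitDataset:
    train: list[TemporalWindow]
    validation: list[TemporalWindow]
    test: list[TemporalWindow]
    group_assignment: dict[str, str] = field(default_factory=dict)
    positive_fractions: dict[str, float] = field(default_factory=dict)


def resample_hourly(
    series: pd.DataFrame, episode: MVEpisode, end: int | None = None
) -> HourlyGrid:
    """Grid a patient's raw vital stream onto hourly cells by within-hour
    means; empty cells are flagged for interpolation.

    ``series`` has columns ``timestamp, variable, value`` (one patient).
    The grid spans episode start to ``end`` (default: episode end), which
    the pipeline sets to the risk-period end so post-extubation windows
    remain constructible.
    """
    t0 = episode.start
    end = episode.end if end is None else end
    n_hours = int((end - t0) // HOUR)
    if n_hours < 1:
        raise EpisodeExclusionError(f"{episode.episode_id}: empty grid span")

    matrix = np.zeros((n_hours, N_VITALS))
    mask = np.ones((n_hours, N_VITALS), dtype=bool)
    sel = series[(series["timestamp"] >= t0) & (series["timestamp"] < t0 + n_hours * HOUR)]
    for j, variable in enumerate(VITALS):
        sub = sel[sel["variable"] == variable]
        if len(sub) == 0:
            raise EpisodeExclusionError(
                f"{episode.episode_id}: no {variable} observations over the episode"
            )
        hours = ((sub["timestamp"].to_numpy() - t0) // HOUR).astype(np.int64)
        sums = np.bincount(hours, weights=sub["value"].to_numpy(), minlength=n_hours)
        counts = np.bincount(hours, minlength=n_hours)
        observed = counts > 0
        matrix[observed, j] = sums[observed] / counts[observed]
        mask[observed, j] = False
    return HourlyGrid(episode.episode_id, t0, matrix, mask)


def interpolate(grid: HourlyGrid) -> HourlyGrid:
    """Fill empty cells: linear interpolation between observed hours,
    nearest-value extension at the edges."""
    matrix = grid.matrix.copy()
    for j, variable in enumerate(VITALS):
        observed = ~grid.imputed_mask[:, j]
        if observed.sum() < 2:
            raise EpisodeExclusionError(
                f"{grid.episode_id}: fewer than 2 observed hours of {variable}"
            )
        idx = np.arange(len(matrix))
        matrix[:, j] = np.interp(idx, idx[observed], matrix[observed, j])
    return HourlyGrid(grid.episode_id, grid.t0, matrix, grid.imputed_mask.copy())


def fit_normalizer(train_windows) -> NormalizationStats:
    """Per-variable mean/sd over every cell of the training windows.

    Accepts a list of :class:`TemporalWindow` or an array broadcastable to
    ``(..., 5)``.
    """
    x = _stack_values(train_windows)
    mean = x.reshape(-1, N_VITALS).mean(axis=0)
    sd = x.reshape(-1, N_VITALS).std(axis=0)
    for j, variable in enumerate(VITALS):
        if sd[j] <= 0:
            raise ValueError(f"zero variance in training data for {variable}")
    return NormalizationStats(mean=mean, sd=sd)


def apply_normalizer(values, stats: NormalizationStats):
    """Standardize; works on a grid, a window, or any ``(..., 5)`` array."""
    if isinstance(values, HourlyGrid):
        return HourlyGrid(
            values.episode_id, values.t0,
            (values.matrix - stats.mean) / stats.sd, values.imputed_mask,
        )
    if isinstance(values, TemporalWindow):
        return TemporalWindow(
            values.episode_id, values.obs_start, values.obs_end,
            (values.values - stats.mean) / stats.sd, dict(values.labels),
        )
    return (np.asarray(values) - stats.mean) / stats.sd


def invert_normalizer(values, stats: NormalizationStats):
    return np.asarray(values) * stats.sd + stats.mean


def _stack_values(windows) -> np.ndarray:
    if isinstance(windows, np.ndarray):
        return windows
    return np.stack([w.values for w in windows])


def make_windows(
    grid: HourlyGrid,
    risk: RiskPeriod,
    vap_events,
    horizons=(6, 12, 24),
    stride_hours: int = 1,
) -> list[TemporalWindow]:
    """Slide 24 h windows over the grid at 1 h stride.

    Emission: ``risk.start <= obs_end < risk.end``.  Censoring: suppressed
    when, for any onset, ``obs_end >= onset`` and ``obs_start < onset + 48 h``.
    Label per horizon h: 1 iff an onset lies in ``(obs_end, obs_end + 60*h]``.
    """
    horizons = tuple(int(h) for h in horizons)
    if not horizons:
        raise ValueError("empty horizon set")
    onsets = sorted(
        int(e) if isinstance(e, (int, np.integer)) else int(e.onset)
        for e in vap_events
    )
    n_hours = grid.matrix.shape[0]
    windows: list[TemporalWindow] = []
    for i in range(0, n_hours - WINDOW_HOURS + 1, stride_hours):
        obs_start = grid.t0 + i * HOUR
        obs_end = obs_start + WINDOW_HOURS * HOUR
        if not (risk.start <= obs_end < risk.end):
            continue
        if any(obs_end >= o and obs_start < o + EVENT_MERGE_GAP for o in onsets):
            continue
        labels = {
            h: int(any(obs_end < o <= obs_end + h * HOUR for o in onsets))
            for h in horizons
        }
        windows.append(
            TemporalWindow(
                grid.episode_id, obs_start, obs_end,
                grid.matrix[i : i + WINDOW_HOURS].copy(), labels,
            )
        )
    return windows


def smote_balance(
    X: np.ndarray,
    y: np.ndarray,
    target_ratio: float = 1.0,
    k: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling in flattened feature space.

    Each synthetic sample is ``x + lam * (z - x)`` for a random minority
    point x, one of its k nearest minority neighbours z (Euclidean, in the
    flattened 120-dim space) and ``lam ~ Uniform(0, 1)``.  Generation stops
    when minority:majority reaches ``target_ratio``.  Originals untouched;
    synthetics appended at the end with the minority label.
    """
    X = np.asarray(X)
    y = np.asarray(y).astype(int)
    shape = X.shape[1:]
    flat = X.reshape(len(X), -1)

    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    minority = 1 if n_pos <= n_neg else 0
    n_min = min(n_pos, n_neg)
    n_maj = max(n_pos, n_neg)
    if n_min < 2:
        raise ValueError("SMOTE requires at least 2 minority samples")
    n_syn = int(round(target_ratio * n_maj)) - n_min
    if n_syn <= 0:
        return X.copy(), y.copy()
    if n_min <= k:
        logger.warning("SMOTE k reduced from %d to %d (minority size)", k, n_min - 1)
        k = n_min - 1

    rng = rng_from_seed(seed)
    min_flat = flat[y == minority]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(min_flat)
    _, neigh = nn.kneighbors(min_flat)  # column 0 is the point itself

    base = rng.integers(0, n_min, size=n_syn)
    pick = rng.integers(1, k + 1, size=n_syn)
    lam = rng.uniform(0.0, 1.0, size=n_syn)
    x0 = min_flat[base]
    z = min_flat[neigh[base, pick]]
    syn = x0 + lam[:, None] * (z - x0)

    X_out = np.concatenate([X, syn.reshape((n_syn,) + shape)])
    y_out = np.concatenate([y, np.full(n_syn, minority, dtype=int)])
    return X_out, y_out


def minority_neighbor_sets(X: np.ndarray, y: np.ndarray, k: int = 5) -> np.ndarray:
    """k-nearest-neighbour indices among minority points (for auditing the
    SMOTE neighbourhood structure)."""
    flat = np.asarray(X).reshape(len(X), -1)
    y = np.asarray(y).astype(int)
    minority = 1 if (y == 1).sum() <= (y == 0).sum() else 0
    min_flat = flat[y == minority]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(min_flat)
    _, neigh = nn.kneighbors(min_flat)
    return neigh[:, 1:]


def _largest_remainder(n: int, fractions) -> list[int]:
    raw = [f * n for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    short = n - sum(base)
    order = np.argsort([b - r for b, r in zip(base, raw)], kind="stable")
    for i in range(short):
        base[int(order[i])] += 1
    return base


def window_is_positive(w: TemporalWindow) -> bool:
    return any(v == 1 for v in w.labels.values())


def split_dataset(
    windows: list[TemporalWindow],
    fractions=(0.6, 0.2, 0.2),
    group_level: str = "episode",
    seed: int = 0,
    tolerance: float = 0.2,
    max_tries: int = 50,
) -> SplitDataset:
    """Stratified 60/20/20 split at the grouping level (default: episode).

    Groups are stratified on whether they contain any positive window; the
    randomization is redrawn (deterministically, up to ``max_tries``) until
    every split's positive-window fraction is within ``tolerance`` relative
    deviation of the global fraction, the first acceptable draw being kept
    (rerandomization design).  SMOTE is *not* applied here — it belongs to
    the training stage, after splitting.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    if group_level == "episode":
        keys = [w.episode_id for w in windows]
    elif group_level == "window":
        keys = [str(i) for i in range(len(windows))]
    else:
        raise ValueError(f"unknown group_level {group_level!r}")

    by_group: dict[str, list[int]] = {}
    for i, key in enumerate(keys):
        by_group.setdefault(key, []).append(i)
    group_pos = {
        g: any(window_is_positive(windows[i]) for i in idxs)
        for g, idxs in by_group.items()
    }
    pos_groups = sorted(g for g, p in group_pos.items() if p)
    neg_groups = sorted(g for g, p in group_pos.items() if not p)
    if len(pos_groups) < 3:
        raise ValueError(
            f"only {len(pos_groups)} positive groups: too few to stratify a "
            "3-way split — generate more data"
        )

    n_total = len(by_group)
    totals = _largest_remainder(n_total, fractions)
    pos_counts = _largest_remainder(len(pos_groups), fractions)
    neg_counts = [t - p for t, p in zip(totals, pos_counts)]

    global_frac = sum(window_is_positive(w) for w in windows) / max(len(windows), 1)
    names = ("train", "validation", "test")
    best: tuple[float, dict] | None = None
    for attempt in range(max_tries):
        rng = rng_from_seed((seed + 7919 * attempt) % (2**31))
        p = [pos_groups[i] for i in rng.permutation(len(pos_groups))]
        q = [neg_groups[i] for i in rng.permutation(len(neg_groups))]
        assignment: dict[str, str] = {}
        ip = iq = 0
        for s, name in enumerate(names):
            for g in p[ip : ip + pos_counts[s]]:
                assignment[g] = name
            ip += pos_counts[s]
            for g in q[iq : iq + neg_counts[s]]:
                assignment[g] = name
            iq += neg_counts[s]
        fracs = {}
        for name in names:
            idxs = [i for g, nm in assignment.items() if nm == name for i in by_group[g]]
            fracs[name] = (
                sum(window_is_positive(windows[i]) for i in idxs) / max(len(idxs), 1)
            )
        dev = max(abs(f - global_frac) / max(global_frac, 1e-12) for f in fracs.values())
        if best is None or dev < best[0]:
            best = (dev, assignment)
        if dev <= tolerance:
            break
    assert best is not None
    _, assignment = best

    buckets: dict[str, list[TemporalWindow]] = {n: [] for n in names}
    for g, idxs in by_group.items():
        for i in idxs:
            buckets[assignment[g]].append(windows[i])
    fracs = {
        n: sum(window_is_positive(w) for w in buckets[n]) / max(len(buckets[n]), 1)
        for n in names
    }
    return SplitDataset(
        train=buckets["train"],
        validation=buckets["validation"],
        test=buckets["test"],
        group_assignment=assignment,
        positive_fractions=fracs,
    )


def windows_to_arrays(
    windows: list[TemporalWindow], horizon: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stack windows into ``(n, 24, 5)`` inputs and 0/1 labels for one horizon."""
    if not windows:
        return np.zeros((0, WINDOW_HOURS, N_VITALS)), np.zeros(0, dtype=int)
    X = np.stack([w.values for w in windows])
    y = np.array([w.labels[horizon] for w in windows], dtype=int)
    return X, y


def windows_index_frame(windows: list[TemporalWindow]) -> pd.DataFrame:
    rows = []
    for w in windows:
        row = {"episode_id": w.episode_id, "obs_start": w.obs_start,
               "obs_end": w.obs_end}
        for h, v in sorted(w.labels.items()):
            row[f"label_{h}h"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def save_windows(windows: list[TemporalWindow], out_dir) -> None:
    """Window-index CSV plus a long-format CSV of the 24x5 matrices."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    windows_index_frame(windows).to_csv(out / "window_index.csv", index=False)
    values = np.stack([w.values for w in windows]) if windows else np.zeros((0, 0, 0))
    flat = values.reshape(len(windows), -1)
    pd.DataFrame(
        flat, columns=[f"h{i:02d}_{v}" for i in range(WINDOW_HOURS) for v in VITALS]
    ).to_csv(out / "window_values.csv", index=False)


def load_windows(in_dir) -> list[TemporalWindow]:
    from pathlib import Path

    d = Path(in_dir)
    index = pd.read_csv(d / "window_index.csv")
    values = pd.read_csv(d / "window_values.csv").to_numpy()
    horizons = [
        int(c.removeprefix("label_").removesuffix("h"))
        for c in index.columns
        if c.startswith("label_")
    ]
    out = []
    for i, row in index.iterrows():
        out.append(
            TemporalWindow(
                str(row["episode_id"]), int(row["obs_start"]), int(row["obs_end"]),
                values[i].reshape(WINDOW_HOURS, N_VITALS),
                {h: int(row[f"label_{h}h"]) for h in horizons},
            )
        )
    return out
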