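"""Shared constants and small helpers used across the pipeline.

Timestamps are integer minutes since ICU admission throughout the package;
rule boundaries (24 h / 48 h / 72 h) are exact integer comparisons, which
avoids float-equality trouble at the boundaries the labelling rules care
about.
"""

from __future__ import annotations

import numpy as np

HOUR = 60  # minutes

#: Canonical vital-sign column order. Every hourly grid, temporal window and
#: flattened feature vector uses this order.
VITALS: tuple[str, ...] = (
    "respiratory_rate",
    "heart_rate",
    "mean_arterial_pressure",
    "temperature",
    "spo2",
)

N_VITALS = len(VITALS)

#: Default prediction horizons in hours.
HORIZONS: tuple[int, ...] = (6, 12, 24)

# Rule constants (minutes)
RISK_START_AFTER_MV = 48 * HOUR     # risk period opens 48 h after MV start
RISK_END_AFTER_EXTUBATION = 72 * HOUR  # and closes 72 h post-extubation
EPISODE_MERGE_GAP = 24 * HOUR       # interruptions < 24 h join one episode
EPISODE_MIN_DURATION = 48 * HOUR    # only episodes > 48 h are eligible
ABX_BEFORE_CULTURE = 72 * HOUR      # antibiotic window: 72 h before culture
ABX_AFTER_CULTURE = 24 * HOUR       # ... to 24 h after culture (inclusive)
EVENT_MERGE_GAP = 48 * HOUR         # VAP onsets < 48 h apart are one event
WINDOW_HOURS = 24                   # observation window length

RESPIRATORY_SPECIMENS = frozenset(
    {"bronchial_aspirate", "BAL", "tracheal_aspirate"}
)


def rng_from_seed(seed: int) -> np.random.Generator:
    """A PCG64 generator; the single entry point for package randomness."""
    return np.random.default_rng(int(seed))
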