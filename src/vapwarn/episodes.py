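"""Mechanical-ventilation episode construction and VAP risk periods.

An MV *episode* is a maximal run of invasive ventilation: segments of one
patient separated by less than 24 h are merged (temporary weaning and
procedural pauses), and only episodes lasting strictly more than 48 h are
eligible for VAP attribution.  The *risk period* of an eligible episode is
the half-open interval from 48 h after MV initiation to 72 h after the end
of the episode; pneumonia with onset in this interval is attributed to the
ventilator.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._common import (
    EPISODE_MERGE_GAP,
    EPISODE_MIN_DURATION,
    HOUR,
    RISK_END_AFTER_EXTUBATION,
    RISK_START_AFTER_MV,
)

SEGMENT_COLUMNS = ["patient_id", "start", "end", "airway"]


@dataclass(frozen=True)
class MVEpisode:
    """A contiguous invasive-ventilation interval (minutes since admission)."""

    episode_id: str
    patient_id: str
    start: int
    end: int
    airway: str

    @property
    def duration_hours(self) -> float:
        return (self.end - self.start) / HOUR


@dataclass(frozen=True)
class RiskPeriod:
    """Half-open interval [start, end) of VAP attributability."""

    episode_id: str
    start: int
    end: int


class SegmentValidationError(ValueError):
    """Raised when a ventilation segment violates end > start."""


def segment_episodes(segments: pd.DataFrame) -> list[MVEpisode]:
    """Merge raw ventilation segments into eligible MV episodes.

    Parameters
    ----------
    segments
        Table with columns ``patient_id, start, end, airway`` (minutes).
        Overlapping segments are permitted and always merged.

    Returns
    -------
    Episodes sorted by (patient_id, start), merged across gaps strictly
    shorter than 24 h and filtered to duration strictly greater than 48 h.
    Episode ids are ``{patient_id}-{k}`` with k counting a patient's
    eligible episodes in time order.
    """
    bad = segments[segments["end"] <= segments["start"]]
    if len(bad):
        row = bad.index[0]
        raise SegmentValidationError(
            f"ventilation segment at row {row!r} has end <= start "
            f"({bad.loc[row, 'end']} <= {bad.loc[row, 'start']})"
        )

    episodes: list[MVEpisode] = []
    for pid, grp in segments.groupby("patient_id", sort=True):
        grp = grp.sort_values(["start", "end"], kind="mergesort")
        merged: list[list] = []  # [start, end, airway]
        for row in grp.itertuples(index=False):
            if merged and row.start - merged[-1][1] < EPISODE_MERGE_GAP:
                merged[-1][1] = max(merged[-1][1], row.end)
            else:
                merged.append([row.start, row.end, row.airway])
        k = 0
        for start, end, airway in merged:
            if end - start > EPISODE_MIN_DURATION:
                episodes.append(
                    MVEpisode(f"{pid}-{k}", str(pid), int(start), int(end), airway)
                )
                k += 1
    episodes.sort(key=lambda e: (e.patient_id, e.start))
    return episodes


def risk_period(episode: MVEpisode) -> RiskPeriod:
    """[start + 48 h, end + 72 h), guaranteed non-empty for eligible episodes."""
    return RiskPeriod(
        episode_id=episode.episode_id,
        start=episode.start + RISK_START_AFTER_MV,
        end=episode.end + RISK_END_AFTER_EXTUBATION,
    )


def episodes_to_frame(episodes: list[MVEpisode]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "episode_id": e.episode_id,
                "patient_id": e.patient_id,
                "start": e.start,
                "end": e.end,
                "airway": e.airway,
                "duration_hours": e.duration_hours,
            }
            for e in episodes
        ],
        columns=["episode_id", "patient_id", "start", "end", "airway", "duration_hours"],
    )
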