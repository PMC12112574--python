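"""Rule-based VAP event annotation and 1:1 matched control selection.

A VAP event is declared when a positive respiratory culture collected inside
an episode's risk period is linked to a new antibiotic regimen targeting
respiratory pathogens started within 72 h before to 24 h after the sample
(both limits inclusive).  The event onset is the earlier of the two times;
candidate events with onsets less than 48 h apart are chained into a single
infection event keeping the earliest onset.

Control selection mirrors the matched-cohort design: each VAP episode is
paired with an eligible episode that never met VAP criteria, matched exactly
on sex and greedily (seeded order, without replacement) on the summed
absolute standardized distance over age, SAPS-II and log MV duration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._common import (
    ABX_AFTER_CULTURE,
    ABX_BEFORE_CULTURE,
    EVENT_MERGE_GAP,
    HOUR,
    RESPIRATORY_SPECIMENS,
    rng_from_seed,
)
from .episodes import MVEpisode, RiskPeriod

logger = logging.getLogger(__name__)

CULTURE_COLUMNS = ["patient_id", "specimen", "charttime", "positive"]
ANTIBIOTIC_COLUMNS = ["patient_id", "drug", "start", "respiratory_target", "is_new"]


@dataclass(frozen=True)
class VAPEvent:
    episode_id: str
    onset: int
    culture_time: int
    antibiotic_time: int


@dataclass(frozen=True)
class MatchedPair:
    vap_episode_id: str
    control_episode_id: str
    match_distance: float


def annotate_vap(
    episode: MVEpisode,
    risk: RiskPeriod,
    cultures: pd.DataFrame,
    antibiotics: pd.DataFrame,
) -> list[VAPEvent]:
    """Apply the culture–antibiotic temporal-linkage rule to one episode.

    ``cultures`` and ``antibiotics`` are event tables for the episode's
    patient (see ``CULTURE_COLUMNS`` / ``ANTIBIOTIC_COLUMNS``).  Returns
    merged events sorted by onset.
    """
    if risk.episode_id != episode.episode_id:
        raise ValueError(
            f"risk period {risk.episode_id!r} does not belong to episode "
            f"{episode.episode_id!r}"
        )

    eligible_cultures = [
        int(c.charttime)
        for c in cultures.itertuples(index=False)
        if bool(c.positive)
        and c.specimen in RESPIRATORY_SPECIMENS
        and risk.start <= int(c.charttime) < risk.end
    ]
    abx_times = [
        int(a.start)
        for a in antibiotics.itertuples(index=False)
        if bool(a.respiratory_target) and bool(a.is_new)
    ]

    candidates: list[tuple[int, int, int]] = []  # (onset, culture, abx)
    for ct in eligible_cultures:
        for at in abx_times:
            if ct - ABX_BEFORE_CULTURE <= at <= ct + ABX_AFTER_CULTURE:
                candidates.append((min(ct, at), ct, at))
    candidates.sort()

    # single-linkage chaining: successive onsets < 48 h apart are one event
    events: list[VAPEvent] = []
    prev_onset: int | None = None
    for onset, ct, at in candidates:
        if prev_onset is not None and onset - prev_onset < EVENT_MERGE_GAP:
            prev_onset = onset  # extend the chain, keep the earliest event
            continue
        events.append(VAPEvent(episode.episode_id, onset, ct, at))
        prev_onset = onset
    return events


def annotate_cohort(
    episodes_and_risks: list[tuple[MVEpisode, RiskPeriod]],
    cultures: pd.DataFrame,
    antibiotics: pd.DataFrame,
) -> list[VAPEvent]:
    """Annotate every episode; event tables are cohort-wide and filtered
    per patient here."""
    out: list[VAPEvent] = []
    cult_by_pid = dict(tuple(cultures.groupby("patient_id", sort=False)))
    abx_by_pid = dict(tuple(antibiotics.groupby("patient_id", sort=False)))
    empty_c = cultures.iloc[0:0]
    empty_a = antibiotics.iloc[0:0]
    for episode, risk in episodes_and_risks:
        out.extend(
            annotate_vap(
                episode,
                risk,
                cult_by_pid.get(episode.patient_id, empty_c),
                abx_by_pid.get(episode.patient_id, empty_a),
            )
        )
    return out


def events_to_frame(events: list[VAPEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "episode_id": e.episode_id,
                "onset": e.onset,
                "culture_time": e.culture_time,
                "antibiotic_time": e.antibiotic_time,
            }
            for e in events
        ],
        columns=["episode_id", "onset", "culture_time", "antibiotic_time"],
    )


def match_controls(
    vap_episodes: list[MVEpisode],
    candidate_episodes: list[MVEpisode],
    demographics: pd.DataFrame,
    caliper: float = 2.0,
    seed: int = 0,
) -> list[MatchedPair]:
    """Greedy 1:1 nearest-neighbour matching without replacement.

    Exact match on sex; distance is the sum of absolute standardized
    differences in age, SAPS-II and log MV duration (standardized over the
    pooled episodes).  VAP episodes are processed in seeded random order;
    episodes with no candidate within ``caliper`` are left unmatched.

    ``demographics`` must have columns ``patient_id, age, sex, saps2``.
    """
    if not candidate_episodes:
        logger.warning("empty control candidate pool: all VAP episodes unmatched")
        return []

    demo = demographics.set_index("patient_id")

    def covariates(eps: list[MVEpisode]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "episode_id": [e.episode_id for e in eps],
                "sex": [demo.loc[e.patient_id, "sex"] for e in eps],
                "age": [float(demo.loc[e.patient_id, "age"]) for e in eps],
                "saps2": [float(demo.loc[e.patient_id, "saps2"]) for e in eps],
                "log_mv": [np.log((e.end - e.start) / HOUR) for e in eps],
            }
        )

    vap_cov = covariates(vap_episodes)
    ctl_cov = covariates(candidate_episodes)
    pooled = pd.concat([vap_cov, ctl_cov], ignore_index=True)
    scale = {
        col: max(float(pooled[col].std(ddof=0)), 1e-12)
        for col in ("age", "saps2", "log_mv")
    }

    rng = rng_from_seed(seed)
    order = rng.permutation(len(vap_cov))
    used: set[int] = set()
    pairs: list[MatchedPair] = []
    for i in order:
        v = vap_cov.iloc[int(i)]
        best_j, best_d = -1, float("inf")
        for j, c in enumerate(ctl_cov.itertuples(index=False)):
            if j in used or c.sex != v["sex"]:
                continue
            d = (
                abs(v["age"] - c.age) / scale["age"]
                + abs(v["saps2"] - c.saps2) / scale["saps2"]
                + abs(v["log_mv"] - c.log_mv) / scale["log_mv"]
            )
            if d < best_d:
                best_j, best_d = j, d
        if best_j >= 0 and best_d <= caliper:
            used.add(best_j)
            pairs.append(
                MatchedPair(v["episode_id"], ctl_cov.iloc[best_j]["episode_id"], best_d)
            )
        else:
            logger.info("no control within caliper for %s", v["episode_id"])
    pairs.sort(key=lambda p: p.vap_episode_id)
    return pairs


def pairs_to_frame(pairs: list[MatchedPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "vap_episode_id": p.vap_episode_id,
                "control_episode_id": p.control_episode_id,
                "match_distance": p.match_distance,
            }
            for p in pairs
        ],
        columns=["vap_episode_id", "control_episode_id", "match_distance"],
    )
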