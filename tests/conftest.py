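import numpy as np
import pandas as pd
import pytest

from vapwarn.episodes import MVEpisode, RiskPeriod

H = 60  # minutes per hour


def hours(x) -> int:
    return int(round(x * H))


@pytest.fixture
def episode():
    """An eligible 200 h episode starting at t=0."""
    e = MVEpisode("P0-0", "P0", 0, hours(200), "endotracheal")
    return e


@pytest.fixture
def risk(episode):
    from vapwarn.episodes import risk_period

    return risk_period(episode)


def culture_frame(rows):
    """rows: list of (charttime_h, specimen, positive)."""
    return pd.DataFrame(
        [
            {"patient_id": "P0", "specimen": sp, "charttime": hours(t), "positive": pos}
            for t, sp, pos in rows
        ],
        columns=["patient_id", "specimen", "charttime", "positive"],
    )


def antibiotic_frame(rows):
    """rows: list of (start_h, respiratory_target, is_new)."""
    return pd.DataFrame(
        [
            {
                "patient_id": "P0",
                "drug": "cefepime",
                "start": hours(t),
                "respiratory_target": rt,
                "is_new": new,
            }
            for t, rt, new in rows
        ],
        columns=["patient_id", "drug", "start", "respiratory_target", "is_new"],
    )


def segment_frame(rows):
    """rows: list of (patient_id, start_h, end_h)."""
    return pd.DataFrame(
        [
            {"patient_id": p, "start": hours(s), "end": hours(e), "airway": "endotracheal"}
            for p, s, e in rows
        ],
        columns=["patient_id", "start", "end", "airway"],
    )
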