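"""MIMIC-like synthetic ICU cohorts with injected pre-VAP signatures.

The generator emulates the five event tables the pipeline consumes —
demographics, ventilation segments, irregular vital-sign streams,
microbiology cultures and antibiotic starts — plus a ground-truth VAP event
list that is written separately and never read by the pipeline itself.

Vital signs follow a mean-reverting (AR(1)-style, exponential-decay)
noise process around a patient-specific baseline with a circadian sinusoid.
Episodes destined to develop VAP receive a convex (accelerating) pre-onset
drift in all five vitals (respiratory rate, heart rate and temperature up;
SpO2 and mean arterial pressure down), plus a heteroscedastic noise
component rising linearly over the same window — physiological instability
precedes and accompanies the overt deterioration.
After onset the signature decays linearly back to baseline (treatment
effect).  Distractor events — positive respiratory cultures with no
qualifying antibiotic, new respiratory antibiotics with no culture, and
events failing the specimen/flag filters — give the annotator true
negatives to reject.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._common import (
    ABX_AFTER_CULTURE,
    ABX_BEFORE_CULTURE,
    HOUR,
    RISK_END_AFTER_EXTUBATION,
    RISK_START_AFTER_MV,
    VITALS,
    rng_from_seed,
)

# Physiological priors: conventional adult ICU values, not calibrated to any
# particular cohort.  Per-vital: baseline mean, mean-reverting noise sd,
# patient-level baseline offset sd, circadian amplitude.
BASELINE_MEAN = {
    "respiratory_rate": 18.0,
    "heart_rate": 80.0,
    "mean_arterial_pressure": 85.0,
    "temperature": 37.0,
    "spo2": 97.0,
}
NOISE_SD = {
    "respiratory_rate": 1.2,
    "heart_rate": 3.0,
    "mean_arterial_pressure": 3.5,
    "temperature": 0.15,
    "spo2": 0.6,
}
PATIENT_OFFSET_SD = {
    "respiratory_rate": 1.0,
    "heart_rate": 3.0,
    "mean_arterial_pressure": 3.0,
    "temperature": 0.1,
    "spo2": 0.5,
}
CIRCADIAN_AMPLITUDE = {
    "respiratory_rate": 0.5,
    "heart_rate": 2.0,
    "mean_arterial_pressure": 2.0,
    "temperature": 0.15,
    "spo2": 0.3,
}
#: Pre-onset drift reached at full ramp, per unit signature amplitude.
SIGNATURE_DRIFT = {
    "respiratory_rate": 6.0,
    "heart_rate": 15.0,
    "mean_arterial_pressure": -5.0,
    "temperature": 1.2,
    "spo2": -4.0,
}

AR1_HOUR_RHO = 0.4         # lag-1 h autocorrelation of the noise process
POST_ONSET_DECAY_HOURS = 24.0
AMPLITUDE_JITTER = 0.07    # per-event multiplicative Uniform(1 +/- jitter)
RAMP_JITTER = 0.15         # per-event ramp-duration Uniform(1 +/- jitter)
RAMP_EXPONENT = 2.0        # convex rise: deterioration accelerates toward onset
INSTABILITY_GAIN = 2.0     # extra noise sd at onset, in units of the base sd
DRIFT_RAMP_FRACTION = 1.0  # overt mean drift spans the full signature ramp
                           # (like the instability envelope)
ANTIBIOTIC_LABELS = ("piperacillin-tazobactam", "cefepime", "meropenem")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 100
    vap_prevalence: float = 0.3
    signature_amplitude: float = 1.0
    signature_ramp_hours: float = 48.0
    sampling_interval_minutes: float = 15.0
    missing_fraction: float = 0.05
    distractor_rate: float = 1.0
    seed: int = 0
    #: median / log-sd of the eligible-episode duration distribution (hours)
    episode_duration_median_hours: float = 84.0
    episode_duration_log_sd: float = 0.25
    #: per-vital drift at unit amplitude; defaults to SIGNATURE_DRIFT
    signature_drifts: dict = field(default_factory=lambda: dict(SIGNATURE_DRIFT))

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not (0.0 <= self.vap_prevalence <= 1.0):
            raise ValueError(f"vap_prevalence {self.vap_prevalence} outside [0, 1]")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValueError(f"missing_fraction {self.missing_fraction} outside [0, 1)")
        if not math.isfinite(self.signature_amplitude) or self.signature_amplitude < 0:
            raise ValueError("signature_amplitude must be finite and >= 0")
        if not math.isfinite(self.signature_ramp_hours) or self.signature_ramp_hours <= 0:
            raise ValueError("signature_ramp_hours must be finite and > 0")
        if (
            not math.isfinite(self.sampling_interval_minutes)
            or self.sampling_interval_minutes <= 0
        ):
            raise ValueError("sampling_interval_minutes must be finite and > 0")
        if self.distractor_rate < 0 or not math.isfinite(self.distractor_rate):
            raise ValueError("distractor_rate must be finite and >= 0")


@dataclass
class CohortTables:
    """The five cohort tables plus the (pipeline-invisible) ground truth."""

    patients: pd.DataFrame
    vitals: pd.DataFrame
    ventilation: pd.DataFrame
    cultures: pd.DataFrame
    antibiotics: pd.DataFrame
    ground_truth: pd.DataFrame


def _ramp_fraction(
    t: np.ndarray, onset: float, ramp_min: float, exponent: float = RAMP_EXPONENT
) -> np.ndarray:
    """Signature intensity in [0, 1]: convex (accelerating) rise over the
    ramp, reaching 1 at onset, then linear decay over
    POST_ONSET_DECAY_HOURS (treatment effect).

    ``exponent=1`` gives the linear envelope used for the physiological-
    instability (variance) component, which precedes the overt mean drift.
    """
    rise = np.clip((t - (onset - ramp_min)) / ramp_min, 0.0, 1.0) ** exponent
    decay_min = POST_ONSET_DECAY_HOURS * HOUR
    fall = np.clip(1.0 - (t - onset) / decay_min, 0.0, 1.0)
    return np.where(t <= onset, rise, fall)


def _simulate_stream(
    rng: np.random.Generator,
    variable: str,
    t: np.ndarray,
    patient_offset: float,
    circadian_phase: float,
    signature: np.ndarray,
    instability: np.ndarray,
    drift: float,
) -> np.ndarray:
    """One vital-sign stream at irregular times ``t`` (minutes)."""
    mu = (
        BASELINE_MEAN[variable]
        + patient_offset
        + CIRCADIAN_AMPLITUDE[variable]
        * np.sin(2.0 * np.pi * (t - circadian_phase) / 1440.0)
        + signature * drift
    )
    sd = NOISE_SD[variable]
    dev = np.empty(len(t))
    eps = rng.standard_normal(len(t))
    prev = rng.standard_normal() * sd
    prev_t = t[0]
    for k in range(len(t)):
        rho = AR1_HOUR_RHO ** ((t[k] - prev_t) / HOUR)
        prev = rho * prev + sd * math.sqrt(max(1.0 - rho * rho, 0.0)) * eps[k]
        dev[k] = prev
        prev_t = t[k]
    # prodromal instability: extra white noise whose sd rises linearly over
    # the pre-onset window (variability precedes the overt mean drift)
    extra = INSTABILITY_GAIN * instability * sd * rng.standard_normal(len(t))
    values = mu + dev + extra
    if variable == "spo2":
        values = np.clip(values, 50.0, 100.0)
    return np.round(values, 1)


def _draw_event_times(
    rng: np.random.Generator, onset: int, risk_end: int
) -> tuple[int, int]:
    """Culture and antibiotic times for a ground-truth event with
    onset = min of the two; both inside the risk period."""
    if rng.random() < 0.5:
        culture = onset
        abx = onset + int(rng.uniform(0, ABX_AFTER_CULTURE))
    else:
        abx = onset
        culture = onset + int(rng.uniform(0, min(48 * HOUR, risk_end - 1 - onset)))
    return culture, min(abx, culture + ABX_AFTER_CULTURE)


def simulate_cohort(config: CohortConfig) -> CohortTables:
    """Generate one cohort; identical config and seed give identical tables."""
    rng = rng_from_seed(config.seed)
    ramp_min = config.signature_ramp_hours * HOUR

    patients, vent_rows = [], []
    culture_rows, abx_rows, gt_rows = [], [], []
    v_pid, v_ts, v_var, v_val = [], [], [], []

    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        sex = "M" if rng.random() < 0.62 else "F"
        age = int(rng.integers(18, 91))
        saps2 = int(np.clip(round(rng.normal(40.0, 12.0)), 0, None))
        patients.append(
            {"patient_id": pid, "age": age, "sex": sex, "saps2": saps2,
             "excluded_cap": False}
        )

        start = int(rng.uniform(0, 48 * HOUR))
        dur_h = float(
            np.clip(
                math.exp(rng.normal(math.log(config.episode_duration_median_hours),
                                    config.episode_duration_log_sd)),
                60.0, 200.0,
            )
        )
        end = start + int(dur_h * HOUR)
        risk_start = start + RISK_START_AFTER_MV
        risk_end = end + RISK_END_AFTER_EXTUBATION
        airway = "endotracheal" if rng.random() < 0.85 else "tracheostomy"

        # ventilation segments: occasionally carve an interior gap < 24 h
        # (merged downstream) and add a short decoy segment (filtered out)
        if rng.random() < 0.25 and dur_h > 30:
            gap_len = int(rng.uniform(1, 12) * HOUR)
            gap_start = int(rng.uniform(start + 10 * HOUR, end - 12 * HOUR - gap_len))
            vent_rows.append({"patient_id": pid, "start": start, "end": gap_start,
                              "airway": airway})
            vent_rows.append({"patient_id": pid, "start": gap_start + gap_len,
                              "end": end, "airway": airway})
        else:
            vent_rows.append({"patient_id": pid, "start": start, "end": end,
                              "airway": airway})
        if rng.random() < 0.15:
            decoy_start = end + int(rng.uniform(26, 40) * HOUR)
            decoy_end = decoy_start + int(rng.uniform(4, 20) * HOUR)
            vent_rows.append({"patient_id": pid, "start": decoy_start,
                              "end": decoy_end, "airway": "endotracheal"})

        # ground-truth VAP event (at most one per episode)
        has_vap = rng.random() < config.vap_prevalence
        onset = None
        if has_vap:
            margin = 2 * HOUR  # keep rule boundaries unambiguous
            onset = int(rng.uniform(risk_start + margin, risk_end - margin))
            culture_t, abx_t = _draw_event_times(rng, onset, risk_end)
            specimen = str(rng.choice(["bronchial_aspirate", "BAL", "tracheal_aspirate"]))
            culture_rows.append({"patient_id": pid, "specimen": specimen,
                                 "charttime": culture_t, "positive": True})
            abx_rows.append({"patient_id": pid,
                             "drug": str(rng.choice(ANTIBIOTIC_LABELS)),
                             "start": abx_t, "respiratory_target": True,
                             "is_new": True})
            gt_rows.append({"patient_id": pid, "episode_id": f"{pid}-0",
                            "onset": onset, "culture_time": culture_t,
                            "antibiotic_time": abx_t})

        # distractors: antibiotics first, then cultures rejected against all
        # qualifying antibiotic times so no spurious pair can form
        qual_abx = [r["start"] for r in abx_rows if r["patient_id"] == pid
                    and r["respiratory_target"] and r["is_new"]]
        real_cultures = [r["charttime"] for r in culture_rows
                         if r["patient_id"] == pid and r["positive"]]
        n_abx_d = rng.poisson(config.distractor_rate / 2.0)
        for _ in range(n_abx_d):
            for _try in range(20):
                at = int(rng.uniform(start, risk_end))
                if all(abs(at - ct) > ABX_BEFORE_CULTURE + ABX_AFTER_CULTURE
                       for ct in real_cultures):
                    abx_rows.append({"patient_id": pid,
                                     "drug": str(rng.choice(ANTIBIOTIC_LABELS)),
                                     "start": at, "respiratory_target": True,
                                     "is_new": True})
                    qual_abx.append(at)
                    break
        n_cult_d = rng.poisson(config.distractor_rate / 2.0)
        for _ in range(n_cult_d):
            for _try in range(20):
                ct = int(rng.uniform(risk_start, risk_end))
                if all(not (ct - ABX_BEFORE_CULTURE <= at <= ct + ABX_AFTER_CULTURE)
                       for at in qual_abx):
                    culture_rows.append(
                        {"patient_id": pid,
                         "specimen": str(rng.choice(
                             ["bronchial_aspirate", "BAL", "tracheal_aspirate"])),
                         "charttime": ct, "positive": True})
                    real_cultures.append(ct)
                    break
        # flag-filtered distractors are harmless anywhere
        if rng.random() < min(config.distractor_rate, 1.0):
            culture_rows.append(
                {"patient_id": pid, "specimen": "other",
                 "charttime": int(rng.uniform(risk_start, risk_end)),
                 "positive": True})
            abx_rows.append(
                {"patient_id": pid, "drug": "cefazolin",
                 "start": int(rng.uniform(start, risk_end)),
                 "respiratory_target": False, "is_new": True})

        # vital-sign streams over [episode start, episode end + 72 h]
        amp = 0.0
        if has_vap:
            amp = config.signature_amplitude * float(
                rng.uniform(1.0 - AMPLITUDE_JITTER, 1.0 + AMPLITUDE_JITTER)
            )
        circadian_phase = float(rng.uniform(0, 1440))
        event_ramp_min = ramp_min * float(
            rng.uniform(1.0 - RAMP_JITTER, 1.0 + RAMP_JITTER)
        )
        for variable in VITALS:
            offset = float(rng.normal(0.0, PATIENT_OFFSET_SD[variable]))
            times, tcur = [], float(start) + float(
                rng.uniform(0, config.sampling_interval_minutes))
            while tcur < risk_end:
                times.append(int(tcur))
                tcur += config.sampling_interval_minutes * float(rng.uniform(0.5, 1.5))
            t = np.array(sorted(set(times)), dtype=np.int64)
            if onset is not None and amp > 0:
                tf = t.astype(float)
                signature = amp * _ramp_fraction(
                    tf, onset, DRIFT_RAMP_FRACTION * event_ramp_min
                )
                instability = amp * _ramp_fraction(
                    tf, onset, event_ramp_min, exponent=1.0
                )
            else:
                signature = np.zeros(len(t))
                instability = signature
            values = _simulate_stream(
                rng, variable, t.astype(float), offset, circadian_phase,
                signature, instability, config.signature_drifts[variable],
            )
            v_pid.extend([pid] * len(t))
            v_ts.append(t)
            v_var.extend([variable] * len(t))
            v_val.append(values)

    vitals = pd.DataFrame(
        {
            "patient_id": v_pid,
            "timestamp": np.concatenate(v_ts) if v_ts else np.array([], dtype=np.int64),
            "variable": v_var,
            "value": np.concatenate(v_val) if v_val else np.array([]),
        }
    )
    if config.missing_fraction > 0:
        vitals = inject_missingness(
            vitals, config.missing_fraction, seed=int(rng.integers(0, 2**31)))

    return CohortTables(
        patients=pd.DataFrame(
            patients, columns=["patient_id", "age", "sex", "saps2", "excluded_cap"]),
        vitals=vitals.reset_index(drop=True),
        ventilation=pd.DataFrame(
            vent_rows, columns=["patient_id", "start", "end", "airway"]),
        cultures=pd.DataFrame(
            culture_rows, columns=["patient_id", "specimen", "charttime", "positive"]),
        antibiotics=pd.DataFrame(
            abx_rows,
            columns=["patient_id", "drug", "start", "respiratory_target", "is_new"]),
        ground_truth=pd.DataFrame(
            gt_rows,
            columns=["patient_id", "episode_id", "onset", "culture_time",
                     "antibiotic_time"]),
    )


def inject_missingness(
    vitals: pd.DataFrame, fraction: float, seed: int
) -> pd.DataFrame:
    """Drop exactly ``round(fraction * n)`` vital records uniformly at random.

    A record is only dropped if doing so leaves no gap of 24 h or more
    between consecutive retained observations of its (patient, variable)
    stream, so hourly windows remain constructible.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError(f"missing fraction {fraction} outside [0, 1)")
    if fraction == 0.0 or len(vitals) == 0:
        return vitals.copy()

    rng = rng_from_seed(seed)
    n_drop = int(round(fraction * len(vitals)))
    df = vitals.reset_index(drop=True)

    # doubly-linked neighbour structure per stream, in time order
    order = df.sort_values(["patient_id", "variable", "timestamp"],
                           kind="mergesort").index.to_numpy()
    pos = {int(idx): k for k, idx in enumerate(order)}
    key = (df["patient_id"].astype(str) + "\x00" + df["variable"].astype(str)).to_numpy()
    ts = df["timestamp"].to_numpy()
    prev_nb = np.full(len(df), -1, dtype=np.int64)
    next_nb = np.full(len(df), -1, dtype=np.int64)
    for k in range(1, len(order)):
        a, b = order[k - 1], order[k]
        if key[a] == key[b]:
            next_nb[a] = b
            prev_nb[b] = a

    limit = 24 * HOUR
    dropped = np.zeros(len(df), dtype=bool)
    n_done = 0
    for idx in rng.permutation(len(df)):
        if n_done >= n_drop:
            break
        p, nx = prev_nb[idx], next_nb[idx]
        if p < 0 or nx < 0:  # keep stream endpoints: preserves coverage span
            continue
        if ts[nx] - ts[p] >= limit:
            continue
        dropped[idx] = True
        next_nb[p] = nx
        prev_nb[nx] = p
        n_done += 1

    return df[~dropped].reset_index(drop=True)


def write_cohort(tables: CohortTables, out_dir) -> None:
    """Write the cohort as CSV files (integer-minute timestamps).  Ground
    truth goes to ``ground_truth.csv``, which the pipeline never reads."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables.patients.to_csv(out / "patients.csv", index=False)
    tables.vitals.to_csv(out / "vitals.csv", index=False)
    tables.ventilation.to_csv(out / "ventilation.csv", index=False)
    tables.cultures.to_csv(out / "cultures.csv", index=False)
    tables.antibiotics.to_csv(out / "antibiotics.csv", index=False)
    tables.ground_truth.to_csv(out / "ground_truth.csv", index=False)


def read_cohort(in_dir) -> CohortTables:
    from pathlib import Path

    d = Path(in_dir)
    return CohortTables(
        patients=pd.read_csv(d / "patients.csv"),
        vitals=pd.read_csv(d / "vitals.csv"),
        ventilation=pd.read_csv(d / "ventilation.csv"),
        cultures=pd.read_csv(d / "cultures.csv"),
        antibiotics=pd.read_csv(d / "antibiotics.csv"),
        ground_truth=pd.read_csv(d / "ground_truth.csv")
        if (d / "ground_truth.csv").exists()
        else pd.DataFrame(),
    )
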