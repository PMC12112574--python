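"""End-to-end orchestration: cohort tables in, evaluation report out.

Stages: episode segmentation -> risk periods -> VAP annotation -> 1:1
matched control selection -> hourly gridding/interpolation -> sliding
windows -> stratified episode-level 60/20/20 split -> normalization (train
stats only) -> SMOTE (train only) -> per-horizon model training ->
precision=recall threshold on validation -> test-set evaluation with
bootstrap CIs -> integrated-gradients attribution.

Every stage draws its randomness from a sub-seed derived from the single
pipeline seed, so one seed fixes the whole run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import annotation, comparators, episodes, evaluation, explain, model, windowing
from ._common import HORIZONS, VITALS
from .synthetic_cohort import CohortTables

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    horizons: tuple = HORIZONS
    model: model.ModelConfig = field(default_factory=model.ModelConfig)
    baselines: tuple = ()           # subset of comparators.BASELINE_KINDS
    smote_target_ratio: float = 1.0
    smote_k: int = 5
    caliper: float = 2.0
    n_bootstrap: int = 100
    n_explain_windows: int = 16
    ig_steps: int = 50
    seed: int = 0


def prepare_windows(
    tables: CohortTables, config: PipelineConfig
) -> tuple[windowing.SplitDataset, dict]:
    """Cohort tables -> labelled windows split at episode level (raw units,
    un-normalized), plus a provenance dict."""
    info: dict = {}
    included = tables.patients[~tables.patients["excluded_cap"].astype(bool)]
    vent = tables.ventilation[
        tables.ventilation["patient_id"].isin(included["patient_id"])
    ]
    eps = episodes.segment_episodes(vent)
    risks = {e.episode_id: episodes.risk_period(e) for e in eps}
    info["n_patients"] = int(len(included))
    info["n_episodes"] = len(eps)

    events = annotation.annotate_cohort(
        [(e, risks[e.episode_id]) for e in eps], tables.cultures, tables.antibiotics
    )
    by_episode: dict[str, list] = {}
    for ev in events:
        by_episode.setdefault(ev.episode_id, []).append(ev)
    info["n_vap_events"] = len(events)
    info["n_vap_episodes"] = len(by_episode)

    vap_eps = [e for e in eps if e.episode_id in by_episode]
    candidates = [e for e in eps if e.episode_id not in by_episode]
    pairs = annotation.match_controls(
        vap_eps, candidates, included, caliper=config.caliper,
        seed=(config.seed + 11) % 2**31,
    )
    info["n_matched_pairs"] = len(pairs)
    keep_ids = {e.episode_id for e in vap_eps} | {p.control_episode_id for p in pairs}
    dataset_eps = [e for e in eps if e.episode_id in keep_ids]

    vitals_by_pid = dict(tuple(tables.vitals.groupby("patient_id", sort=False)))
    windows: list[windowing.TemporalWindow] = []
    excluded = 0
    for e in dataset_eps:
        risk = risks[e.episode_id]
        series = vitals_by_pid.get(e.patient_id)
        if series is None:
            excluded += 1
            continue
        try:
            grid = windowing.resample_hourly(series, e, end=risk.end)
            grid = windowing.interpolate(grid)
        except windowing.EpisodeExclusionError as exc:
            logger.info("excluded: %s", exc)
            excluded += 1
            continue
        windows.extend(
            windowing.make_windows(
                grid, risk, by_episode.get(e.episode_id, []), config.horizons
            )
        )
    info["n_dataset_episodes"] = len(dataset_eps)
    info["n_excluded_episodes"] = excluded
    info["n_windows"] = len(windows)

    split = windowing.split_dataset(windows, seed=(config.seed + 23) % 2**31)
    info["positive_fractions"] = dict(split.positive_fractions)
    return split, info


def run_pipeline(
    tables: CohortTables, config: PipelineConfig, out_dir: str | Path | None = None
) -> dict:
    """Run the whole study on one cohort; returns a JSON-serializable report."""
    split, info = prepare_windows(tables, config)
    stats = windowing.fit_normalizer(split.train)
    norm = {
        name: [windowing.apply_normalizer(w, stats) for w in part]
        for name, part in (
            ("train", split.train),
            ("validation", split.validation),
            ("test", split.test),
        )
    }

    report: dict = {
        "cohort": info,
        "normalizer": {
            "mean": {v: float(stats.mean[j]) for j, v in enumerate(VITALS)},
            "sd": {v: float(stats.sd[j]) for j, v in enumerate(VITALS)},
        },
        "horizons": {},
    }
    if tables.ground_truth is not None and len(tables.ground_truth):
        report["annotation_audit"] = annotation_audit(tables, config)

    for horizon in config.horizons:
        h_report: dict = {}
        Xtr, ytr = windowing.windows_to_arrays(norm["train"], horizon)
        Xval, yval = windowing.windows_to_arrays(norm["validation"], horizon)
        Xte, yte = windowing.windows_to_arrays(norm["test"], horizon)
        Xb, yb = windowing.smote_balance(
            comparators.featurize(Xtr), ytr,
            target_ratio=config.smote_target_ratio, k=config.smote_k,
            seed=(config.seed + 31 + horizon) % 2**31,
        )
        Xb = comparators.unflatten(Xb)
        h_report["n_train"] = int(len(Xb))
        h_report["n_validation"] = int(len(Xval))
        h_report["n_test"] = int(len(Xte))

        mcfg = model.ModelConfig(
            **{
                **{k: getattr(config.model, k) for k in (
                    "n_recurrent_layers", "cells_per_layer", "dropout_rate",
                    "learning_rate", "batch_size", "max_epochs", "patience")},
                "seed": (config.model.seed + horizon) % 2**31,
            }
        )
        fitted = model.build_model(mcfg, n_features=Xb.shape[-1])
        fitted = model.train(fitted, (Xb, yb), (Xval, yval), mcfg)
        h_report["n_params"] = fitted.n_params
        h_report["best_epoch"] = fitted.history["best_epoch"]
        h_report["val_auprc"] = fitted.history["best_val_auprc"]

        scores_by_model = {"lstm": fitted.predict_proba(Xte)}
        thresholds = {
            "lstm": model.select_threshold(
                fitted.predict_proba(Xval), yval, horizon
            ).threshold
        }
        for kind in config.baselines:
            base = comparators.train_baseline(
                kind, (comparators.featurize(Xb), yb),
                seed=(config.seed + 47) % 2**31,
            )
            scores_by_model[kind] = base.predict_proba(comparators.featurize(Xte))
            thresholds[kind] = model.select_threshold(
                base.predict_proba(comparators.featurize(Xval)), yval, horizon
            ).threshold

        h_report["evaluation"] = evaluation.evaluation_report(
            scores_by_model, yte, thresholds, horizon,
            n_boot=config.n_bootstrap, seed=(config.seed + 59) % 2**31,
        )
        for kind in config.baselines:
            delta, p = evaluation.compare_auprc(
                scores_by_model["lstm"], scores_by_model[kind], yte,
                n=config.n_bootstrap, seed=(config.seed + 67) % 2**31,
            )
            h_report.setdefault("auprc_comparison", {})[kind] = {
                "delta_auprc": delta, "p_value": p,
            }

        pos_idx = np.where(yte == 1)[0][: config.n_explain_windows]
        if len(pos_idx):
            maps = [
                explain.integrated_gradients(fitted, Xte[i], n_steps=config.ig_steps)
                for i in pos_idx
            ]
            imp = explain.aggregate_importance(maps)
            h_report["explainability"] = {
                "feature_importance": imp.values,
                "rule": imp.rule,
                "mean_completeness_gap": float(
                    np.mean([m.completeness_gap for m in maps])
                ),
            }
        report["horizons"][str(horizon)] = h_report

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report


def annotation_audit(tables: CohortTables, config: PipelineConfig) -> dict:
    """Compare annotated events against the generator's ground truth
    (synthetic cohorts only; never feeds back into the pipeline)."""
    vent = tables.ventilation
    eps = episodes.segment_episodes(vent)
    risks = [(e, episodes.risk_period(e)) for e in eps]
    events = annotation.annotate_cohort(risks, tables.cultures, tables.antibiotics)
    gt = tables.ground_truth
    matched = 0
    claimed = set()
    for row in gt.itertuples(index=False):
        for k, ev in enumerate(events):
            if k in claimed:
                continue
            if ev.episode_id == row.episode_id and int(ev.onset) == int(row.onset):
                matched += 1
                claimed.add(k)
                break
    return {
        "n_ground_truth": int(len(gt)),
        "n_annotated": len(events),
        "n_recovered": matched,
        "recovery_rate": matched / len(gt) if len(gt) else float("nan"),
        "n_false_events": len(events) - matched,
    }
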