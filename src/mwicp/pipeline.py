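"""End-to-end orchestration of the ICP-monitoring pipeline.

One :class:`PipelineConfig` drives the whole chain: simulate (or ingest)
-> align -> preprocess -> dataset variants -> features -> correlation +
OSS -> regression -> report. Every stage is a pure function of its inputs,
the config and the seed, so a rerun with the same config reproduces the
same numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import PLACEMENTS, SENSOR_IDS, FrequencyGrid, InvalidConfigError
from .datasets import create_variants, split_trials
from .features import FEATURE_CLASSES, extract_feature_table
from .io_sync import align_reference, write_trial
from .preprocess import process_trial
from .regression import evaluate, registry, select_best, train_models
from .selection import aggregate_by_class, correlate_table, oss_select
from .synth import CouplingModel, SimulationConfig, simulate_trial

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "count_feature_records", "feature_matrix"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run; defaults mirror the lab protocol.

    f_th 50 MHz, OSS threshold 0.8 with p < 0.001, 5-fold trial-grouped CV
    and an 80/10/10 trial split; five repeated trials per placement with
    the 2-6 GHz / 2001-point grid, a 3 Hz sweep rate and a 0-60 mmHg ramp.
    """

    out_dir: str | None = None
    sensors: tuple[str, ...] = SENSOR_IDS
    placements: tuple[str, ...] = PLACEMENTS
    n_repeats: int = 5
    duration_s: float = 120.0
    grid: FrequencyGrid = field(default_factory=FrequencyGrid)
    coupling: CouplingModel = field(default_factory=CouplingModel)
    f_th_mhz: float = 50.0
    onset_threshold: float = 0.1
    oss_threshold: float = 0.8
    alpha: float = 0.001
    cv_folds: int = 5
    models: tuple[str, ...] | None = None
    seed: int = 0
    write_trials: bool = False
    write_features: bool = False

    def validate(self) -> None:
        if self.f_th_mhz <= 0:
            raise InvalidConfigError("f_th must be positive")
        if not 0 < self.oss_threshold <= 1:
            raise InvalidConfigError("OSS threshold must be in (0, 1]")
        if self.n_repeats < 1 or self.duration_s <= 0:
            raise InvalidConfigError("need positive repeats and duration")
        unknown = set(self.sensors) - set(SENSOR_IDS)
        if unknown:
            raise InvalidConfigError(f"unknown sensors {sorted(unknown)}")
        unknown = set(self.placements) - set(PLACEMENTS)
        if unknown:
            raise InvalidConfigError(f"unknown placements {sorted(unknown)}")
        if self.models is not None:
            missing = set(self.models) - set(registry())
            if missing:
                raise InvalidConfigError(f"unknown presets {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "grid" in raw:
            raw["grid"] = FrequencyGrid(**raw["grid"])
        if "coupling" in raw:
            raw["coupling"] = CouplingModel(**raw["coupling"])
        for key in ("sensors", "placements", "models"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class PipelineResult:
    feature_table: pd.DataFrame
    correlation: pd.DataFrame
    selections: dict[str, object]
    splits: dict[str, object]
    sensor_reports: dict[str, dict]
    out_dir: Path | None


def count_feature_records(table: pd.DataFrame) -> int:
    """Number of (sensor, trial, placement, variant, class) feature records."""
    keys = ["sensor", "trial", "placement", "variant", "class"]
    return int(table.groupby(keys).ngroups)


def feature_matrix(table: pd.DataFrame, classes, variant: str = "Ds1"):
    """Pivot the tidy table into (X, y, groups) for regression.

    Rows are sweeps of the chosen variant, columns the selected classes in
    catalog order; groups carry the global trial id for trial-disjoint
    fold construction.
    """
    classes = [c for c in FEATURE_CLASSES if c in set(classes)]
    if not classes:
        raise InvalidConfigError("empty feature selection")
    df = table[table["variant"] == variant].copy()
    df["uid"] = (df["sensor"] + "/" + df["placement"] + "/"
                 + df["trial"].astype(str))
    wide = df.pivot_table(index=["uid", "sweep_index"], columns="class",
                          values="value")
    wide = wide[classes].dropna()
    labels = df.drop_duplicates(["uid", "sweep_index"]).set_index(
        ["uid", "sweep_index"])["p_mmHg"]
    y = labels.loc[wide.index].to_numpy()
    groups = wide.index.get_level_values("uid").to_numpy()
    return wide.to_numpy(), y, groups


def _trial_seed(root: int, k: int) -> int:
    return int(np.random.SeedSequence([root, k]).generate_state(1)[0]
               % (2 ** 31))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full campaign described by ``config``."""
    config.validate()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    tables = []
    counter = 0
    trial_uids: dict[str, list[str]] = {s: [] for s in config.sensors}
    for sensor in config.sensors:
        for placement in config.placements:
            for rep in range(1, config.n_repeats + 1):
                counter += 1
                sim = SimulationConfig(
                    sensor_id=sensor,
                    trial_index=rep,
                    placement=placement,
                    grid=config.grid,
                    coupling=config.coupling,
                    duration_s=config.duration_s,
                    seed=_trial_seed(config.seed, counter),
                )
                trial = simulate_trial(sim)
                if config.write_trials and out_dir:
                    write_trial(
                        trial,
                        out_dir / "trials" / f"{sensor}_{placement}_{rep}")
                aligned = align_reference(trial)
                processed = process_trial(
                    aligned, f_th_mhz=config.f_th_mhz,
                    onset_threshold=config.onset_threshold)
                # distinct trial indices across placements for bookkeeping
                processed.trial_index = (
                    config.placements.index(placement) * config.n_repeats
                    + rep)
                table = extract_feature_table(
                    processed, create_variants(processed))
                tables.append(table)
                trial_uids[sensor].append(
                    f"{sensor}/{placement}/{processed.trial_index}")
    feature_table = pd.concat(tables, ignore_index=True)

    correlation = correlate_table(feature_table)
    selections, splits, sensor_reports = {}, {}, {}
    for sensor in config.sensors:
        sub = correlation[correlation["sensor"] == sensor]
        per_class = aggregate_by_class(sub)
        selection = oss_select(per_class, threshold=config.oss_threshold,
                               alpha=config.alpha)
        selections[sensor] = selection
        if not selection.selected:
            sensor_reports[sensor] = {"error": "OSS selected no features"}
            continue

        split = split_trials(trial_uids[sensor], seed=config.seed)
        splits[sensor] = split
        sensor_table = feature_table[feature_table["sensor"] == sensor]
        X, y, groups = feature_matrix(sensor_table, selection.selected)
        role_of = split.roles

        def mask(role):
            return np.array([role_of[g] == role for g in groups])

        tr, va, te = mask("train"), mask("validation"), mask("test")
        fitted = train_models(
            X[tr], y[tr], groups[tr],
            presets=list(config.models) if config.models else None,
            cv_folds=config.cv_folds, seed=config.seed)
        val_reports = {
            name: evaluate(fm, X[va], y[va],
                           test_trial_ids=set(groups[va]))
            for name, fm in fitted.items()
        }
        best = select_best({n: r for n, r in val_reports.items()})
        test_report = evaluate(fitted[best], X[te], y[te],
                               test_trial_ids=set(groups[te]))
        sensor_reports[sensor] = {
            "selected_classes": list(selection.selected),
            "best_preset": best,
            "validation": {
                n: {"mae": r.mae, "rmse": r.rmse, "r2": r.r2}
                for n, r in val_reports.items()
            },
            "test": {
                "mae": test_report.mae,
                "rmse": test_report.rmse,
                "r2": test_report.r2,
                "n": int(te.sum()),
                "prediction_speed_obs_per_s":
                    test_report.prediction_speed_obs_per_s,
                "training_time_s": test_report.training_time_s,
            },
        }

    if out_dir:
        correlation.to_csv(out_dir / "correlation.csv", index=False)
        if config.write_features:
            feature_table.to_csv(out_dir / "features.csv", index=False)
        summary = {
            "n_feature_records": count_feature_records(feature_table),
            "sensors": sensor_reports,
            "seed": config.seed,
        }
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str)

    return PipelineResult(
        feature_table=feature_table,
        correlation=correlation,
        selections=selections,
        splits=splits,
        sensor_reports=sensor_reports,
        out_dir=out_dir,
    )
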