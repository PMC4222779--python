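"""End-to-end analysis runs: simulate/load -> error analysis -> ANOVA ->
trouble flagging -> subset allometry, with every output regenerable from
the (config, seed) pair.

All files for one run are written under a directory named by the first 12
hex digits of the SHA-256 of the canonical config YAML, so identical
configurations land in identical directories and re-runs are byte-for-byte
reproducible (no timestamps are written).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .allometry import DEFAULT_ANCHORS, SubsetComparison, subset_experiment
from .error_analysis import (
    AnovaTable,
    TroubleThresholds,
    deviation_from_mean,
    flag_trouble,
    interobserver_error,
    intraobserver_error,
    placement_anova_by_age,
    summarize_error,
)
from .exceptions import ConfigError, EmbryomorphError
from .io import read_dataset, write_dataset
from .scheme import TrialDataset
from .simulate import SimParams, simulate_dataset

log = logging.getLogger("embryomorph.pipeline")

ALL_STAGES = ("simulate", "errors", "anova", "flagging", "allometry")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Input is either a list of coordinate files or (default) a simulation;
    ``error_observers`` (intra/inter error, flagging, allometry) defaults to
    the experienced observers, ``anova_observers`` to all observers.
    """

    sim: SimParams = field(default_factory=SimParams)
    input_files: tuple[str, ...] | None = None
    input_format: str = "csv"
    stages: tuple[str, ...] = ALL_STAGES
    error_observers: tuple[str, ...] | None = None
    anova_observers: tuple[str, ...] | None = None
    thresholds: TroubleThresholds = field(default_factory=TroubleThresholds)
    anchor_ids: tuple[int, int, int] = DEFAULT_ANCHORS
    out_dir: str = "runs"
    seed: int | None = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages {sorted(unknown)}")
        if self.input_format not in ("csv", "tps"):
            raise ConfigError(f"unknown input format {self.input_format!r}")

    def resolved_seed(self) -> int:
        return self.sim.seed if self.seed is None else int(self.seed)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["sim"] = yaml.safe_load(self.sim.to_yaml())
        d["thresholds"] = dataclasses.asdict(self.thresholds)
        for key in ("stages", "anchor_ids"):
            d[key] = list(d[key])
        if d["input_files"] is not None:
            d["input_files"] = list(d["input_files"])
        if d["error_observers"] is not None:
            d["error_observers"] = list(d["error_observers"])
        if d["anova_observers"] is not None:
            d["anova_observers"] = list(d["anova_observers"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        if "sim" in d and d["sim"] is not None:
            d["sim"] = SimParams.from_yaml(yaml.safe_dump(d["sim"]))
        if "thresholds" in d and d["thresholds"] is not None:
            d["thresholds"] = TroubleThresholds(**d["thresholds"])
        for key in ("stages", "anchor_ids", "input_files", "error_observers",
                    "anova_observers"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


@dataclass
class RunReport:
    """Summary of one pipeline run; every number regenerates from
    (config, seed)."""

    run_dir: Path
    config_hash: str
    seed: int
    design: tuple
    anova: dict[str, AnovaTable] | None = None
    flagged: set[str] | None = None
    comparison: SubsetComparison | None = None
    files: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        payload: dict = {
            "provenance": {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "version": __version__,
            },
            "design": {
                "n_specimens_per_age": list(self.design[0]),
                "n_observers": self.design[1],
                "n_trials": self.design[2],
            },
            "files": self.files,
        }
        if self.anova is not None:
            payload["anova"] = {
                age: {
                    "df": t.df,
                    "sum_sq": t.sum_sq,
                    "f_value": t.f_value,
                    "p_value": t.p_value,
                }
                for age, t in self.anova.items()
            }
        if self.flagged is not None:
            payload["flagged_landmarks"] = sorted(self.flagged)
        if self.comparison is not None:
            payload["allometry"] = {
                "pct_variance": self.comparison.pct_variance,
                "anchor_ids": list(self.comparison.anchor_ids),
                "delta_cs": self.comparison.delta_cs,
                "max_angle_deg": {
                    name: self.comparison.max_angle(name)
                    for name in self.comparison.fits
                    if name != "all"
                },
            }
        return json.dumps(payload, indent=2, sort_keys=True)


def _experienced_default(dataset: TrialDataset) -> tuple[str, ...]:
    obs = dataset.observers
    return obs[:-1] if len(obs) > 1 else obs


def run(config: RunConfig) -> RunReport:
    """Execute the configured stages in order and write all outputs.

    Any stage failure is re-raised with the stage name attached; outputs of
    completed stages remain on disk.
    """
    chash = config.config_hash()
    run_dir = Path(config.out_dir) / f"run_{chash}"
    run_dir.mkdir(parents=True, exist_ok=True)
    seed = config.resolved_seed()
    (run_dir / "config.yaml").write_text(config.to_yaml(), encoding="utf-8")

    report = RunReport(run_dir=run_dir, config_hash=chash, seed=seed, design=())
    stage = "input"
    try:
        if config.input_files is not None:
            log.info("stage %s: reading %d file(s)", stage, len(config.input_files))
            dataset = read_dataset(config.input_files, format=config.input_format)
        else:
            stage = "simulate"
            log.info("stage %s: seed=%d design=%s", stage, seed, config.sim.design)
            dataset, truth = simulate_dataset(config.sim, seed=seed)
            if "simulate" in config.stages:
                p = write_dataset(dataset, run_dir / "dataset.csv", "csv")
                report.files["dataset"] = p.name
                (run_dir / "ground_truth.json").write_text(
                    truth.to_json(), encoding="utf-8"
                )
                report.files["ground_truth"] = "ground_truth.json"
        report.design = dataset.design
        log.info("dataset: %d configurations, design %s", len(dataset.configurations),
                 dataset.design)

        error_obs = config.error_observers or _experienced_default(dataset)
        anova_obs = config.anova_observers or dataset.observers
        intra = inter = None

        if "errors" in config.stages or "flagging" in config.stages:
            stage = "errors"
            log.info("stage %s: observers=%s", stage, error_obs)
            intra = intraobserver_error(dataset, pool_bilateral=True)
            inter = interobserver_error(dataset, observers=error_obs)
            if "errors" in config.stages:
                intra.to_csv(run_dir / "intraobserver.csv", index=False)
                inter.to_csv(run_dir / "interobserver.csv", index=False)
                summarize_error(intra, ["age", "observer", "landmark"]).to_csv(
                    run_dir / "intraobserver_summary.csv", index=False
                )
                report.files["intraobserver"] = "intraobserver.csv"
                report.files["interobserver"] = "interobserver.csv"

        if "anova" in config.stages:
            stage = "anova"
            log.info("stage %s: observers=%s", stage, anova_obs)
            dev = deviation_from_mean(dataset, observers=anova_obs)
            report.anova = placement_anova_by_age(dev)
            frames = [t.to_frame() for t in report.anova.values()]
            if frames:
                import pandas as pd

                pd.concat(frames).to_csv(run_dir / "anova.csv", index=False)
                report.files["anova"] = "anova.csv"

        if "flagging" in config.stages:
            stage = "flagging"
            intra_exp = intra[intra["observer"].isin(error_obs)]
            report.flagged = flag_trouble(intra_exp, inter, config.thresholds)
            log.info("stage %s: flagged %s", stage, sorted(report.flagged))

        if "allometry" in config.stages:
            stage = "allometry"
            log.info("stage %s: anchors=%s", stage, config.anchor_ids)
            report.comparison = subset_experiment(
                dataset, observers=error_obs, anchor_ids=config.anchor_ids
            )
            report.comparison.angles.to_csv(run_dir / "vector_angles.csv", index=False)
            report.files["vector_angles"] = "vector_angles.csv"
            for name, vec in report.comparison.vectors.items():
                vec.to_csv(run_dir / f"vectors_{name}.csv", index=False)

        stage = "report"
        (run_dir / "report.json").write_text(report.to_json(), encoding="utf-8")
        report.files["report"] = "report.json"
        log.info("run complete: %s", run_dir)
        return report
    except EmbryomorphError as exc:
        raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
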