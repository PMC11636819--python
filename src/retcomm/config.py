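"""Structured pipeline configuration (YAML) with validation.

Unknown keys are rejected and out-of-range cutoffs raise a
:class:`ConfigError` naming the offending key, so a config echoed into
a run report can be replayed exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .io_formats import QCThresholds, QC_WHOLE_RETINA, QC_PURIFIED_RGC
from .scoring import ScoringParams

__all__ = ["PipelineConfig", "ConfigError", "parse_config", "write_config"]


class ConfigError(ValueError):
    pass


QC_PRESETS = {"whole_retina": QC_WHOLE_RETINA, "purified_rgc": QC_PURIFIED_RGC}

DEFAULT_STAGES = {
    "simulate": True,
    "qc": True,
    "profile": True,
    "score": True,
    "differential": True,
    "dynamics": True,
}

_SECTIONS = {"paths", "qc", "scoring", "partition", "cutoffs", "stages", "simulate", "seed"}
_PATH_KEYS = {"atlas_dir", "lr_pairs", "network", "out_dir"}
_CUTOFF_KEYS = {"ds", "fc", "epsilon", "min_cells"}
_SCORING_KEYS = {"alpha", "gamma", "K", "detection_min", "score_min", "score_any_timepoint"}
_SIM_KEYS = {
    "n_cell_types", "n_high", "n_low", "n_genes", "cells_per_group",
    "n_planted", "n_decoys", "n_loops", "receptor_boost", "noise_sd",
}


@dataclass
class PipelineConfig:
    paths: dict = field(default_factory=lambda: {"out_dir": "retcomm_out"})
    qc_preset: str = "whole_retina"
    qc_thresholds: QCThresholds | None = None
    scoring: ScoringParams = field(default_factory=ScoringParams)
    partition_high: tuple[str, ...] = ()
    partition_low: tuple[str, ...] = ()
    ds_cutoff: float = 0.25
    fc_cutoff: float = 1.2
    epsilon: float = 0.01
    min_cells: int = 10
    seed: int = 0
    stages: dict = field(default_factory=lambda: dict(DEFAULT_STAGES))
    simulate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ds_cutoff <= 0:
            raise ConfigError(f"cutoffs.ds must be > 0, got {self.ds_cutoff}")
        if self.fc_cutoff < 1:
            raise ConfigError(f"cutoffs.fc must be >= 1, got {self.fc_cutoff}")
        if self.epsilon < 0:
            raise ConfigError(f"cutoffs.epsilon must be >= 0, got {self.epsilon}")
        if self.min_cells < 1:
            raise ConfigError(f"cutoffs.min_cells must be >= 1, got {self.min_cells}")
        unknown = set(self.stages) - set(DEFAULT_STAGES)
        if unknown:
            raise ConfigError(f"unknown stage toggle(s): {sorted(unknown)}")
        for key in DEFAULT_STAGES:
            self.stages.setdefault(key, DEFAULT_STAGES[key])
        if self.qc_preset not in QC_PRESETS:
            raise ConfigError(f"qc.preset must be one of {sorted(QC_PRESETS)}")

    @property
    def qc(self) -> QCThresholds:
        return self.qc_thresholds if self.qc_thresholds is not None else QC_PRESETS[self.qc_preset]

    def echo(self) -> dict:
        """JSON-safe dump of every effective setting."""
        qc = asdict(self.qc)
        qc = {k: ("inf" if isinstance(v, float) and math.isinf(v) else v) for k, v in qc.items()}
        return {
            "paths": dict(self.paths),
            "qc": qc,
            "scoring": asdict(self.scoring),
            "partition": {"high": list(self.partition_high), "low": list(self.partition_low)},
            "cutoffs": {"ds": self.ds_cutoff, "fc": self.fc_cutoff,
                        "epsilon": self.epsilon, "min_cells": self.min_cells},
            "seed": self.seed,
            "stages": dict(self.stages),
            "simulate": dict(self.simulate),
        }


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {section}: {sorted(unknown)}")


def parse_config(path: str | Path) -> PipelineConfig:
    """Read a YAML config, apply defaults, and validate."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys("config", raw, _SECTIONS)

    paths = dict(raw.get("paths") or {})
    _check_keys("paths", paths, _PATH_KEYS)
    paths.setdefault("out_dir", "retcomm_out")

    qc_raw = dict(raw.get("qc") or {})
    _check_keys("qc", qc_raw, {"preset"} | set(QCThresholds.__dataclass_fields__))
    preset = qc_raw.pop("preset", "whole_retina")
    thresholds = None
    if qc_raw:
        base = asdict(QC_PRESETS.get(preset, QC_WHOLE_RETINA))
        base.update({k: (math.inf if v == "inf" else v) for k, v in qc_raw.items()})
        try:
            thresholds = QCThresholds(**base)
        except ValueError as exc:
            raise ConfigError(f"qc: {exc}") from exc

    scoring_raw = dict(raw.get("scoring") or {})
    _check_keys("scoring", scoring_raw, _SCORING_KEYS)
    try:
        scoring = ScoringParams(**scoring_raw)
    except ValueError as exc:
        raise ConfigError(f"scoring: {exc}") from exc

    part = dict(raw.get("partition") or {})
    _check_keys("partition", part, {"high", "low"})

    cut = dict(raw.get("cutoffs") or {})
    _check_keys("cutoffs", cut, _CUTOFF_KEYS)

    stages = dict(raw.get("stages") or {})
    sim = dict(raw.get("simulate") or {})
    _check_keys("simulate", sim, _SIM_KEYS)

    return PipelineConfig(
        paths=paths,
        qc_preset=preset,
        qc_thresholds=thresholds,
        scoring=scoring,
        partition_high=tuple(part.get("high", ())),
        partition_low=tuple(part.get("low", ())),
        ds_cutoff=float(cut.get("ds", 0.25)),
        fc_cutoff=float(cut.get("fc", 1.2)),
        epsilon=float(cut.get("epsilon", 0.01)),
        min_cells=int(cut.get("min_cells", 10)),
        seed=int(raw.get("seed", 0)),
        stages=stages,
        simulate=sim,
    )


def write_config(config: PipelineConfig, path: str | Path) -> None:
    payload = config.echo()
    payload["qc"] = {"preset": config.qc_preset, **(
        {} if config.qc_thresholds is None else {
            k: v for k, v in payload["qc"].items() if k != "preset"
        })}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
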