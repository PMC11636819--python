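"""End-to-end orchestration: simulate/load -> QC -> profiles -> score
-> filter -> differential -> dynamics, with a machine-readable report.

Every stage logs its wall time and contributes counts to
``report.json``; identical config + seed reproduce identical artifacts.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import synthetic
from .config import PipelineConfig
from .differential import SurvivalPartition, differential_table, nonredundant_rollup
from .dynamics import dynamics_table
from .io_formats import load_expression, qc_filter_cells, save_expression, write_results
from .profiles import profiles_to_frame, summarize_profiles
from .scoring import (SignalingNetwork, filter_interactions, load_lr_pairs,
                      save_lr_pairs, score_interactions)

__all__ = ["run_pipeline", "StageError"]

log = logging.getLogger("retcomm")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    out_dir = Path(config.paths["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.echo(), "stages": {}, "counts": {}}
    state: dict = {}

    order = ["simulate", "qc", "profile", "score", "differential", "dynamics"]
    for stage in order:
        if not config.stages.get(stage, True):
            report["stages"][stage] = {"skipped": True}
            log.info("stage %s skipped", stage)
            continue
        t0 = time.perf_counter()
        try:
            _STAGES[stage](config, state, report, out_dir)
        except Exception as exc:  # noqa: BLE001 - report which stage failed
            raise StageError(stage, exc) from exc
        dt = time.perf_counter() - t0
        report["stages"][stage] = {"skipped": False, "seconds": round(dt, 4)}
        log.info("stage %s done in %.2fs", stage, dt)

    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def _stage_simulate(config, state, report, out_dir):
    design = synthetic.default_design(seed=config.seed, **config.simulate)
    atlas, truth = synthetic.simulate_experiment(design)
    network = synthetic.build_synthetic_network(truth, extra_edges=0, seed=config.seed)
    pairs = synthetic.lr_database(truth)
    sim_dir = out_dir / "sim"
    save_expression(atlas, sim_dir)
    synthetic.export_truth(truth, sim_dir / "truth.json")
    network.save(sim_dir / "network.tsv")
    save_lr_pairs(pairs, sim_dir / "lr_pairs.tsv")
    state.update(atlas=atlas, truth=truth, network=network, pairs=pairs, design=design)
    state["partition"] = SurvivalPartition(
        high=[n for n, c in design.rgc_subclasses if c == "high"],
        low=[n for n, c in design.rgc_subclasses if c == "low"],
    )
    report["counts"]["cells_simulated"] = atlas.n_cells
    report["counts"]["planted"] = len(truth.planted)
    report["counts"]["decoys"] = len(truth.decoys)


def _load_inputs(config, state):
    atlas_dir = Path(config.paths["atlas_dir"])
    state["atlas"] = load_expression(
        atlas_dir / "matrix.mtx", atlas_dir / "features.tsv",
        atlas_dir / "barcodes.tsv", atlas_dir / "cell_metadata.tsv",
    )
    state["network"] = SignalingNetwork.load(config.paths["network"])
    state["pairs"] = load_lr_pairs(config.paths["lr_pairs"])
    state["partition"] = SurvivalPartition(config.partition_high, config.partition_low)


def _stage_qc(config, state, report, out_dir):
    if "atlas" not in state:
        _load_inputs(config, state)
    atlas, qc_report = qc_filter_cells(state["atlas"], config.qc)
    state["atlas"] = atlas
    report["counts"]["cells_retained"] = qc_report["n_retained"]
    report["counts"]["qc"] = qc_report


def _stage_profile(config, state, report, out_dir):
    if "atlas" not in state:
        _load_inputs(config, state)
    state["profiles"] = summarize_profiles(state["atlas"], group_by="mixed")
    write_results({"profiles": profiles_to_frame(state["profiles"])}, out_dir)
    report["counts"]["profiles"] = len(state["profiles"])


def _stage_score(config, state, report, out_dir):
    scores = score_interactions(
        state["profiles"], state["pairs"], state["network"], config.scoring
    )
    retained = filter_interactions(scores, state["profiles"], config.scoring)
    state["scores"] = scores
    state["retained"] = retained
    write_results({"scores": scores, "scores_retained": retained}, out_dir)
    report["counts"]["pairs_scored"] = int(
        scores[["sender", "receiver", "ligand", "receptor"]].drop_duplicates().shape[0]
    )
    report["counts"]["pairs_retained"] = int(
        retained[["sender", "receiver", "ligand", "receptor"]].drop_duplicates().shape[0]
    )


def _stage_differential(config, state, report, out_dir):
    partition = state["partition"]
    profiles_12h = [p for p in state["profiles"] if p.timepoint == "12h"] or None
    diff = differential_table(
        state["scores"], partition, profiles_12h,
        cutoff=config.ds_cutoff, detection_min=config.scoring.detection_min,
    )
    state["differential"] = diff
    write_results({"differential": diff}, out_dir)
    report["counts"]["class_tally"] = diff["class"].value_counts().to_dict()
    report["counts"]["timing_tally"] = (
        diff.loc[diff["class"] == "protective", "timing"].value_counts().to_dict()
    )
    report["counts"]["mode_tally"] = (
        diff.loc[diff["class"] == "protective", "mode"].value_counts().to_dict()
    )
    report["counts"]["nonredundant"] = nonredundant_rollup(diff)


def _stage_dynamics(config, state, report, out_dir):
    atlas = state["atlas"]
    dyn = dynamics_table(
        state["retained"], atlas.timepoints,
        fc_cutoff=config.fc_cutoff, epsilon=config.epsilon,
    )
    state["dynamics"] = dyn
    write_results({"dynamics": dyn}, out_dir)
    report["counts"]["variable_interactions"] = int(dyn["variable"].sum())
    report["counts"]["dynamic_groups"] = dyn.loc[dyn["variable"], "group"].value_counts().to_dict()


_STAGES = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "profile": _stage_profile,
    "score": _stage_score,
    "differential": _stage_differential,
    "dynamics": _stage_dynamics,
}
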