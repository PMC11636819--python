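"""Differential interaction statistics between high- and low-survival
receiver subclasses.

The core statistic for a (sender, LR pair) family is

    ds_lr = mean over high subclasses of max-over-timepoints S_LR
          - mean over low  subclasses of max-over-timepoints S_LR

An interaction is called protective when ds_lr exceeds the cutoff
(default 0.25), or stronger-in-low below the negative cutoff — a class
the source data left empty but which must exist.  The module also
classifies protective interactions as preset (the high-vs-low gap is
already present before injury) or induced (the gap appears only
afterwards), assigns an autocrine/paracrine mode from where the ligand
is produced at 12h, and adjusts subclass proportions by an overall
survival rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import CellTypeProfile

__all__ = [
    "SurvivalPartition",
    "SubclassSurvival",
    "compute_ds_lr",
    "classify_protective",
    "classify_preset_induced",
    "classify_signaling_mode",
    "adjust_subclass_survival",
    "differential_table",
    "nonredundant_rollup",
]

DS_CUTOFF_DEFAULT = 0.25


@dataclass(frozen=True)
class SurvivalPartition:
    high: frozenset[str]
    low: frozenset[str]

    def __init__(self, high, low):
        object.__setattr__(self, "high", frozenset(high))
        object.__setattr__(self, "low", frozenset(low))
        if not self.high or not self.low:
            raise ValueError("both partition sides must be non-empty")
        if self.high & self.low:
            raise ValueError(f"subclasses in both sides: {sorted(self.high & self.low)}")

    def swapped(self) -> "SurvivalPartition":
        return SurvivalPartition(self.low, self.high)


def _max_over_timepoints(
    scores: pd.DataFrame, subclasses: frozenset[str], missing_as_zero: bool
) -> dict[str, float]:
    """Per-subclass max of S_LR across timepoints for one family."""
    out: dict[str, float] = {}
    present = scores.groupby("receiver")["S_LR"].max()
    for sub in subclasses:
        if sub in present.index:
            out[sub] = float(present[sub])
        elif missing_as_zero:
            warnings.warn(f"no scores for subclass {sub!r}; treated as 0", stacklevel=3)
            out[sub] = 0.0
    return out


def compute_ds_lr(
    scores: pd.DataFrame,
    partition: SurvivalPartition,
    missing_as_zero: bool = True,
) -> float:
    """ds_lr for one (sender, LR pair) family of scores.

    ``scores`` must carry the columns ``receiver, timepoint, S_LR`` for
    a single sender and pair, with receivers drawn from the partition's
    subclasses.  Missing (subclass, timepoint) entries are treated as 0
    by default (configurable to NaN-skip).
    """
    high = _max_over_timepoints(scores, partition.high, missing_as_zero)
    low = _max_over_timepoints(scores, partition.low, missing_as_zero)
    if not high:
        raise ValueError("no scores for any high-survival subclass")
    if not low:
        raise ValueError("no scores for any low-survival subclass")
    return float(np.mean(list(high.values())) - np.mean(list(low.values())))


def classify_protective(ds_lr: float, cutoff: float = DS_CUTOFF_DEFAULT) -> str:
    """protective / neutral / stronger_in_low by strict comparison to
    +-cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if ds_lr > cutoff:
        return "protective"
    if ds_lr < -cutoff:
        return "stronger_in_low"
    return "neutral"


def classify_preset_induced(
    scores: pd.DataFrame,
    partition: SurvivalPartition,
    cutoff: float = DS_CUTOFF_DEFAULT,
    control: str = "control",
    missing_as_zero: bool = True,
) -> tuple[float, float, str]:
    """(delta_pre, delta_post, timing) for one family.

    delta_pre compares subclass means of S_LR at control; delta_post
    compares means of the max over post-injury timepoints.  Timing is
    preset when the gap is already >= cutoff at control, induced when
    it only reaches the cutoff after injury, else neither.
    """
    if control not in set(scores["timepoint"]):
        raise ValueError(f"no {control!r} timepoint in scores")
    pre = scores[scores["timepoint"] == control]
    post = scores[scores["timepoint"] != control]

    def side_mean(frame: pd.DataFrame, subs: frozenset[str]) -> float:
        vals = _max_over_timepoints(frame, subs, missing_as_zero)
        if not vals:
            raise ValueError("partition side entirely missing")
        return float(np.mean(list(vals.values())))

    delta_pre = side_mean(pre, partition.high) - side_mean(pre, partition.low)
    delta_post = side_mean(post, partition.high) - side_mean(post, partition.low)
    if delta_pre >= cutoff:
        timing = "preset"
    elif delta_post >= cutoff:
        timing = "induced"
    else:
        timing = "neither"
    return delta_pre, delta_post, timing


def classify_signaling_mode(
    ligand: str,
    profiles_12h: list[CellTypeProfile],
    rgc_groups: set[str],
    detection_min: float = 0.10,
) -> str:
    """autocrine / paracrine / both from where the ligand is produced
    at the 12h timepoint.

    ``rgc_groups`` names the receiver-side (subclass) groups; all other
    profile groups count as "other" producer types.  Returns
    ``undetected`` (flagged) when the ligand is expressed nowhere.
    """
    in_rgc = any(
        p.detection_rate.get(ligand, 0.0) >= detection_min
        for p in profiles_12h if p.group in rgc_groups
    )
    in_other = any(
        p.detection_rate.get(ligand, 0.0) >= detection_min
        for p in profiles_12h if p.group not in rgc_groups
    )
    if in_rgc and in_other:
        return "both"
    if in_rgc:
        return "autocrine"
    if in_other:
        return "paracrine"
    warnings.warn(f"ligand {ligand!r} undetected everywhere at 12h", stacklevel=2)
    return "undetected"


@dataclass
class SubclassSurvival:
    subclass: str
    share_sham: float
    share_cond: float
    overall_survival: float

    @property
    def adjusted_share(self) -> float:
        return self.share_cond * self.overall_survival

    @property
    def est_subclass_survival(self) -> float:
        return self.adjusted_share / self.share_sham


def adjust_subclass_survival(
    counts_sham: dict[str, float],
    counts_cond: dict[str, float],
    overall_survival: float,
) -> list[SubclassSurvival]:
    """Estimate per-subclass survival from composition shifts.

    Subclass shares in the injured condition are scaled by the overall
    survival rate (e.g. 0.638 for control injury, 0.854 with the
    protective receptor overexpressed), then divided by the uninjured
    shares.  The adjusted shares sum to the overall survival exactly.
    """
    missing = [s for s, c in counts_sham.items() if c <= 0]
    if missing:
        raise ValueError(f"subclass absent from sham: {missing}")
    extra = set(counts_cond) - set(counts_sham)
    if extra:
        raise ValueError(f"subclass absent from sham: {sorted(extra)}")
    total_sham = float(sum(counts_sham.values()))
    total_cond = float(sum(counts_cond.values()))
    if total_cond <= 0:
        raise ValueError("no cells in injured condition")
    out = []
    for sub in counts_sham:
        out.append(
            SubclassSurvival(
                subclass=sub,
                share_sham=counts_sham[sub] / total_sham,
                share_cond=counts_cond.get(sub, 0.0) / total_cond,
                overall_survival=overall_survival,
            )
        )
    return out


# ---------------------------------------------------------------------------
# table-level drivers
# ---------------------------------------------------------------------------

def differential_table(
    scores: pd.DataFrame,
    partition: SurvivalPartition,
    profiles_12h: list[CellTypeProfile] | None = None,
    cutoff: float = DS_CUTOFF_DEFAULT,
    detection_min: float = 0.10,
    control: str = "control",
    missing_as_zero: bool = True,
) -> pd.DataFrame:
    """Full differential analysis over a score table whose receivers are
    RGC subclasses.

    Returns one row per (sender, ligand, receptor) with columns
    ``ds_lr, class, delta_pre, delta_post, timing, mode`` (mode is
    ``unknown`` when no 12h profiles are supplied; timing is only
    assigned to protective interactions).
    """
    subclasses = partition.high | partition.low
    rgc_scores = scores[scores["receiver"].isin(subclasses)]
    rows = []
    for (sender, ligand, receptor), grp in rgc_scores.groupby(
        ["sender", "ligand", "receptor"], sort=True
    ):
        ds = compute_ds_lr(grp, partition, missing_as_zero)
        cls = classify_protective(ds, cutoff)
        delta_pre, delta_post, timing = classify_preset_induced(
            grp, partition, cutoff, control, missing_as_zero
        )
        if cls != "protective":
            timing = "neither"
        if profiles_12h is not None:
            mode = classify_signaling_mode(ligand, profiles_12h, set(subclasses), detection_min)
        else:
            mode = "unknown"
        rows.append((sender, ligand, receptor, ds, cls, delta_pre, delta_post, timing, mode))
    return pd.DataFrame(
        rows,
        columns=["sender", "ligand", "receptor", "ds_lr", "class",
                 "delta_pre", "delta_post", "timing", "mode"],
    )


def nonredundant_rollup(diff: pd.DataFrame) -> dict[str, int]:
    """Two de-duplication conventions for counting protective
    interactions across senders: by (ligand, receptor) identity alone
    and by (sender, ligand, receptor)."""
    prot = diff[diff["class"] == "protective"]
    return {
        "protective_by_pair": int(prot[["ligand", "receptor"]].drop_duplicates().shape[0]),
        "protective_by_sender_pair": int(
            prot[["sender", "ligand", "receptor"]].drop_duplicates().shape[0]
        ),
    }
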