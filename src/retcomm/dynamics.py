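"""Temporal dynamics of interaction scores: variability flagging and
assignment to four archetypal response groups.

An interaction is "variable" when the fold change between some two
timepoints exceeds a cutoff (default 1.2).  Variable trajectories over
the four ordered timepoints are assigned, by correlation with fixed
templates, to: transiently repressed, transiently activated, rapidly
sustained, or slowly activated.  Template matching (rather than ad hoc
clustering) keeps the grouping deterministic; a k=4 hierarchical mode
is available for atlas-style outputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance

__all__ = [
    "TEMPLATES",
    "GROUP_ORDER",
    "flag_variable_interactions",
    "assign_dynamic_group",
    "dynamics_table",
    "cluster_trajectories",
]

# shapes transcribed from the verbal archetypes; matched after z-scoring
GROUP_ORDER = ["transient_repressed", "transient_activated", "rapid_sustained", "slow_activated"]
TEMPLATES: dict[str, np.ndarray] = {
    "transient_repressed": np.array([0.0, -1.0, 0.0, 0.0]),
    "transient_activated": np.array([0.0, 1.0, 0.0, 0.0]),
    "rapid_sustained": np.array([-1.0, 1.0, 1.0, 1.0]),
    "slow_activated": np.array([-1.0, -1.0 / 3.0, 1.0 / 3.0, 1.0]),
}

FC_CUTOFF_DEFAULT = 1.2
EPSILON_DEFAULT = 0.01


def flag_variable_interactions(
    scores: np.ndarray | list[float],
    fc_cutoff: float = FC_CUTOFF_DEFAULT,
    epsilon: float = EPSILON_DEFAULT,
) -> tuple[float, bool]:
    """Max pairwise fold change of a trajectory and the variability flag.

    fc_max is the largest (S(t1)+epsilon)/(S(t2)+epsilon) over ordered
    timepoint pairs with the ratio taken larger over smaller; variable
    iff fc_max > fc_cutoff.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise ValueError("need >= 2 timepoints")
    if (s + epsilon <= 0).any():
        raise ValueError("scores + epsilon must be positive")
    fc_max = float((s.max() + epsilon) / (s.min() + epsilon))
    return fc_max, fc_max > fc_cutoff


def _zscore(s: np.ndarray) -> np.ndarray | None:
    sd = s.std()
    if sd == 0:
        return None
    return (s - s.mean()) / sd


def assign_dynamic_group(
    trajectory: np.ndarray | list[float],
    fc_cutoff: float = FC_CUTOFF_DEFAULT,
    epsilon: float = EPSILON_DEFAULT,
    templates: dict[str, np.ndarray] | None = None,
) -> str:
    """Group label for one 4-timepoint trajectory; ``none`` when the
    trajectory is not variable.  Ties go to the first template in
    ``GROUP_ORDER``."""
    s = np.asarray(trajectory, dtype=float)
    _, variable = flag_variable_interactions(s, fc_cutoff, epsilon)
    if not variable:
        return "none"
    z = _zscore(s)
    if z is None:
        return "none"
    templates = templates or TEMPLATES
    if any(len(t) != s.size for t in templates.values()):
        raise ValueError("template length must match trajectory length")
    best_name, best_r = "none", -np.inf
    for name in GROUP_ORDER:
        t = _zscore(np.asarray(templates[name], dtype=float))
        r = float(np.mean(z * t))  # Pearson r of two z-scored vectors
        if r > best_r + 1e-15:
            best_name, best_r = name, r
    return best_name


def dynamics_table(
    scores: pd.DataFrame,
    timepoints: tuple[str, ...],
    fc_cutoff: float = FC_CUTOFF_DEFAULT,
    epsilon: float = EPSILON_DEFAULT,
) -> pd.DataFrame:
    """Per-(sender, receiver, pair) trajectory summary over a score
    table: S per timepoint, fc_max, the variability flag and the group."""
    rows = []
    for (sender, receiver, ligand, receptor), grp in scores.groupby(
        ["sender", "receiver", "ligand", "receptor"], sort=True
    ):
        by_tp = grp.set_index("timepoint")["S_LR"]
        traj = np.array([float(by_tp.get(t, 0.0)) for t in timepoints])
        fc_max, variable = flag_variable_interactions(traj, fc_cutoff, epsilon)
        group = (
            assign_dynamic_group(traj, fc_cutoff, epsilon)
            if variable and len(timepoints) == 4 else ("none" if not variable else "unassigned")
        )
        rows.append((sender, receiver, ligand, receptor, *traj, fc_max, variable, group))
    cols = ["sender", "receiver", "ligand", "receptor"] + [f"S_{t}" for t in timepoints] + [
        "fc_max", "variable", "group"]
    return pd.DataFrame(rows, columns=cols)


def cluster_trajectories(trajectories: np.ndarray, k: int = 4) -> np.ndarray:
    """Optional hierarchical grouping (average linkage, correlation
    distance) of z-scored trajectories into k clusters; returns labels."""
    z = np.array([_zscore(t) if _zscore(t) is not None else np.zeros_like(t, dtype=float)
                  for t in np.asarray(trajectories, dtype=float)])
    dist = scipy.spatial.distance.pdist(z, metric="correlation")
    dist = np.nan_to_num(dist, nan=1.0)
    link = scipy.cluster.hierarchy.linkage(dist, method="average")
    return scipy.cluster.hierarchy.fcluster(link, t=k, criterion="maxclust")
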