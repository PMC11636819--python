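"""Per-(group, timepoint) expression summaries and the fold-change /
background comparisons built on them.

Counts are normalized per cell to a common library size (counts per
10k) before averaging, so cells with deep libraries do not dominate a
group mean.  Detection rate is the fraction of cells in a group with a
nonzero raw count for the gene and is normalization-invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io_formats import ExpressionAtlas

__all__ = [
    "CellTypeProfile",
    "summarize_profiles",
    "profiles_to_frame",
    "profiles_from_frame",
    "compute_log2fc_table",
    "compare_lr_vs_background",
    "count_expressed_lr_genes",
    "correlate_profiles",
]

LIBRARY_TARGET = 10_000.0


@dataclass
class CellTypeProfile:
    """Mean normalized expression and detection rate for one
    (group, timepoint) cell population."""

    group: str
    timepoint: str
    mean_expr: pd.Series      # gene -> mean CP10k
    detection_rate: pd.Series  # gene -> fraction of cells with count > 0
    n_cells: int

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("profile requires n_cells >= 1")
        if ((self.detection_rate < 0) | (self.detection_rate > 1)).any():
            raise ValueError("detection_rate outside [0, 1]")


def summarize_profiles(
    atlas: ExpressionAtlas,
    group_by: str = "mixed",
) -> list[CellTypeProfile]:
    """One profile per (group, timepoint) with at least one cell.

    ``group_by`` is ``cell_type``, ``subclass`` (RGC cells only) or
    ``mixed`` (subclass for RGC cells, cell type otherwise — the
    grouping used for scoring).  Empty groups are omitted with a
    warning.
    """
    labels = atlas.group_labels(group_by)
    counts = atlas.counts.tocsc()
    libsize = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    zero_lib = libsize == 0
    if zero_lib.any():
        warnings.warn(f"{int(zero_lib.sum())} cells with zero counts", stacklevel=2)
        libsize[zero_lib] = 1.0
    # CP10k, column-scaled once; detection uses the raw counts
    norm = counts.multiply(LIBRARY_TARGET / libsize).tocsc()

    out: list[CellTypeProfile] = []
    groups = [g for g in pd.unique(labels.dropna())]
    for tp in atlas.timepoints:
        tp_mask = (atlas.cells["timepoint"] == tp).to_numpy()
        for group in groups:
            mask = tp_mask & (labels == group).to_numpy()
            n = int(mask.sum())
            if n == 0:
                warnings.warn(f"empty group ({group}, {tp}); profile omitted", stacklevel=2)
                continue
            sub_norm = norm[:, mask]
            sub_raw = counts[:, mask]
            mean = np.asarray(sub_norm.mean(axis=1)).ravel()
            det = np.asarray((sub_raw > 0).sum(axis=1)).ravel() / n
            out.append(
                CellTypeProfile(
                    group=str(group),
                    timepoint=tp,
                    mean_expr=pd.Series(mean, index=atlas.genes),
                    detection_rate=pd.Series(det, index=atlas.genes),
                    n_cells=n,
                )
            )
    return out


def profiles_to_frame(profiles: list[CellTypeProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for gene in p.mean_expr.index:
            rows.append((p.group, p.timepoint, gene,
                         float(p.mean_expr[gene]), float(p.detection_rate[gene]), p.n_cells))
    return pd.DataFrame(
        rows, columns=["group", "timepoint", "gene", "mean_expr", "detection_rate", "n_cells"]
    )


def profiles_from_frame(frame: pd.DataFrame) -> list[CellTypeProfile]:
    out = []
    for (group, tp), grp in frame.groupby(["group", "timepoint"], sort=False):
        out.append(
            CellTypeProfile(
                group=str(group),
                timepoint=str(tp),
                mean_expr=pd.Series(grp["mean_expr"].to_numpy(), index=grp["gene"].tolist()),
                detection_rate=pd.Series(grp["detection_rate"].to_numpy(), index=grp["gene"].tolist()),
                n_cells=int(grp["n_cells"].iloc[0]),
            )
        )
    return out


def compute_log2fc_table(
    profiles: list[CellTypeProfile],
    pseudocount: float = 1.0,
    detection_min: float = 0.10,
    control: str = "control",
) -> pd.DataFrame:
    """Per-gene log2 fold change of each post-injury timepoint against
    control, within one group's profile set.

    Only genes detected above ``detection_min`` in the group at some
    timepoint are kept.  Returns columns ``gene, group,
    log2fc_<timepoint>..., max_abs_log2fc``.
    """
    by_group: dict[str, dict[str, CellTypeProfile]] = {}
    for p in profiles:
        by_group.setdefault(p.group, {})[p.timepoint] = p

    frames = []
    for group, tps in by_group.items():
        if control not in tps:
            raise ValueError(f"group {group!r} lacks a {control!r} profile")
        post = [t for t in tps if t != control]
        if not post:
            raise ValueError(f"group {group!r} has no post-injury timepoints")
        det_any = pd.concat([tps[t].detection_rate for t in tps], axis=1).max(axis=1)
        genes = det_any[det_any > detection_min].index
        base = tps[control].mean_expr[genes]
        data = {"gene": genes, "group": group}
        fc_cols = []
        for t in post:
            col = f"log2fc_{t}"
            fc_cols.append(col)
            data[col] = np.log2((tps[t].mean_expr[genes] + pseudocount) / (base + pseudocount))
        frame = pd.DataFrame(data).reset_index(drop=True)
        frame["max_abs_log2fc"] = frame[fc_cols].abs().max(axis=1)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def compare_lr_vs_background(
    fc_table: pd.DataFrame, lr_gene_set: set[str]
) -> tuple[float, float]:
    """Two-sided two-sample KS test on ``max_abs_log2fc`` of
    LR-annotated genes against all remaining genes."""
    is_lr = fc_table["gene"].isin(lr_gene_set)
    lr_vals = fc_table.loc[is_lr, "max_abs_log2fc"].to_numpy()
    bg_vals = fc_table.loc[~is_lr, "max_abs_log2fc"].to_numpy()
    if len(lr_vals) == 0 or len(bg_vals) == 0:
        raise ValueError("both the LR group and the background must be non-empty")
    res = scipy.stats.ks_2samp(lr_vals, bg_vals, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def count_expressed_lr_genes(
    profiles: list[CellTypeProfile],
    ligand_genes: set[str],
    receptor_genes: set[str],
    detection_min: float = 0.10,
) -> pd.DataFrame:
    """Per group, how many database ligands / receptors are detected at
    >= ``detection_min`` (and in at least one cell) at any timepoint."""
    det_any: dict[str, pd.Series] = {}
    for p in profiles:
        cur = det_any.get(p.group)
        det_any[p.group] = p.detection_rate if cur is None else np.maximum(cur, p.detection_rate)
    rows = []
    for group, det in det_any.items():
        n_l = int(sum(0.0 < det.get(g, 0.0) and det.get(g, 0.0) >= detection_min
                      for g in ligand_genes))
        n_r = int(sum(0.0 < det.get(g, 0.0) and det.get(g, 0.0) >= detection_min
                      for g in receptor_genes))
        rows.append((group, n_l, n_r))
    return pd.DataFrame(rows, columns=["group", "n_ligands", "n_receptors"])


def correlate_profiles(a: CellTypeProfile, b: CellTypeProfile) -> float:
    """Pearson correlation of log1p mean expression over shared genes."""
    shared = a.mean_expr.index.intersection(b.mean_expr.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared genes, got {len(shared)}")
    x = np.log1p(a.mean_expr[shared].to_numpy(dtype=float))
    y = np.log1p(b.mean_expr[shared].to_numpy(dtype=float))
    r = scipy.stats.pearsonr(x, y)
    return float(r.statistic)
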