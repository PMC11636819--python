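"""Ligand-receptor interaction scoring with network support and
feedback-loop adjustment.

For each (sender group, receiver group, LR pair, timepoint) the score is

    S0   = sqrt(e_L * e_R) * (alpha + (1 - alpha) * n_support)
    S_LR = S0 + gamma * loop_strength * (1 - S0)   if S0 > 0 else 0

where ``e_L``/``e_R`` are the ligand/receptor mean expressions scaled by
the gene's maximum over all (group, timepoint) profiles, ``n_support``
is the fraction of the receptor's downstream target genes detected in
the receiver, and ``loop_strength`` is the best base score among
reverse-direction pairs that close a feedback loop through the
signaling/regulatory network.  All quantities live in [0, 1] and
``S_LR >= S0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .profiles import CellTypeProfile

__all__ = [
    "LRPair",
    "SignalingNetwork",
    "ScoringParams",
    "load_lr_pairs",
    "save_lr_pairs",
    "network_support",
    "downstream_targets",
    "find_lr_loops",
    "score_interactions",
    "filter_interactions",
    "aggregate_celltype_scores",
    "combine_score",
]

EDGE_KINDS = ("signaling", "regulatory")

SCORE_COLUMNS = [
    "sender", "receiver", "ligand", "receptor", "timepoint",
    "e_L", "e_R", "n_support", "S0", "loop_strength", "S_LR",
]


@dataclass(frozen=True)
class LRPair:
    ligand: str
    receptor: str


@dataclass
class SignalingNetwork:
    """Directed gene-gene network with signaling and regulatory edges."""

    edges: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for src, dst, kind in self.edges:
            if src == dst:
                raise ValueError(f"self-edge on {src!r}")
            if kind not in EDGE_KINDS:
                raise ValueError(f"unknown edge kind {kind!r}")

    @property
    def nodes(self) -> set[str]:
        out = set()
        for src, dst, _ in self.edges:
            out.add(src)
            out.add(dst)
        return out

    def signaling_adjacency(self) -> dict[str, list[str]]:
        adj: dict[str, list[str]] = {}
        for src, dst, kind in self.edges:
            if kind == "signaling":
                adj.setdefault(src, []).append(dst)
        return adj

    def regulatory_adjacency(self) -> dict[str, list[str]]:
        adj: dict[str, list[str]] = {}
        for src, dst, kind in self.edges:
            if kind == "regulatory":
                adj.setdefault(src, []).append(dst)
        return adj

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["source", "target", "edge_kind"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SignalingNetwork":
        return cls([(r.source, r.target, r.edge_kind) for r in frame.itertuples()])

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path) -> "SignalingNetwork":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass(frozen=True)
class ScoringParams:
    """Knobs of the scoring formula and the two retention criteria.

    ``score_any_timepoint`` selects how the score criterion is applied:
    the default keeps a pair whose S_LR reaches ``score_min`` at at
    least one timepoint; ``False`` demands it at every timepoint.
    """

    alpha: float = 0.5
    gamma: float = 0.5
    K: int = 3
    detection_min: float = 0.10
    score_min: float = 0.5
    score_any_timepoint: bool = True

    def __post_init__(self) -> None:
        for name in ("alpha", "gamma"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.K < 0:
            raise ValueError("K must be >= 0")
        if not 0.0 <= self.detection_min <= 1.0:
            raise ValueError("detection_min must be in [0, 1]")
        if not 0.0 <= self.score_min <= 1.0:
            raise ValueError("score_min must be in [0, 1]")


def load_lr_pairs(path: str | Path) -> list[LRPair]:
    frame = pd.read_csv(path, sep="\t")
    pairs = [LRPair(str(r.ligand), str(r.receptor)) for r in frame.itertuples()]
    if len(set(pairs)) != len(pairs):
        raise ValueError("duplicate LR pair in database")
    return pairs


def save_lr_pairs(pairs: list[LRPair], path: str | Path) -> None:
    pd.DataFrame([(p.ligand, p.receptor) for p in pairs],
                 columns=["ligand", "receptor"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# network reachability
# ---------------------------------------------------------------------------

def downstream_targets(receptor: str, network: SignalingNetwork, k_max: int) -> set[str]:
    """Target genes reachable from ``receptor`` via at most ``k_max``
    signaling edges followed by exactly one regulatory edge."""
    sig = network.signaling_adjacency()
    reg = network.regulatory_adjacency()
    reachable = {receptor}
    frontier = {receptor}
    for _ in range(k_max):
        nxt = set()
        for node in frontier:
            nxt.update(sig.get(node, ()))
        frontier = nxt - reachable
        if not frontier:
            break
        reachable |= frontier
    targets: set[str] = set()
    for node in reachable:
        targets.update(reg.get(node, ()))
    return targets


def network_support(
    receptor: str,
    receiver_profile: CellTypeProfile,
    network: SignalingNetwork,
    params: ScoringParams,
) -> float:
    """Fraction of the receptor's downstream targets detected in the
    receiver group; 0 when the receptor has no targets."""
    targets = downstream_targets(receptor, network, params.K)
    if not targets:
        return 0.0
    det = receiver_profile.detection_rate
    n_hit = sum(1 for t in targets if det.get(t, 0.0) >= params.detection_min)
    return n_hit / len(targets)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def combine_score(e_l: float, e_r: float, n_support: float, loop: float,
                  alpha: float, gamma: float) -> tuple[float, float]:
    """Return (S0, S_LR) from the components; the closed-form core of
    the scorer, kept standalone so properties can be tested directly."""
    s0 = np.sqrt(e_l * e_r) * (alpha + (1.0 - alpha) * n_support)
    if s0 <= 0.0:
        return 0.0, 0.0
    return float(s0), float(s0 + gamma * loop * (1.0 - s0))


class _ProfileIndex:
    """Lookups over a list of per-(group, timepoint) profiles."""

    def __init__(self, profiles: list[CellTypeProfile]):
        self.by_key: dict[tuple[str, str], CellTypeProfile] = {}
        for p in profiles:
            key = (p.group, p.timepoint)
            if key in self.by_key:
                raise ValueError(f"duplicate profile for {key}")
            self.by_key[key] = p
        self.groups = sorted({p.group for p in profiles})
        self.timepoints = list(dict.fromkeys(p.timepoint for p in profiles))
        self._gene_max: dict[str, float] = {}
        for p in profiles:
            for gene, val in p.mean_expr.items():
                if val > self._gene_max.get(gene, 0.0):
                    self._gene_max[gene] = float(val)

    def scaled_expr(self, gene: str, group: str, timepoint: str) -> float:
        gmax = self._gene_max.get(gene, 0.0)
        if gmax <= 0.0:
            return 0.0
        prof = self.by_key.get((group, timepoint))
        if prof is None:
            return 0.0
        return float(prof.mean_expr.get(gene, 0.0)) / gmax

    def detection(self, gene: str, group: str, timepoint: str) -> float:
        prof = self.by_key.get((group, timepoint))
        if prof is None:
            return 0.0
        return float(prof.detection_rate.get(gene, 0.0))

    def has_gene(self, gene: str) -> bool:
        return gene in self._gene_max


def find_lr_loops(
    pair: LRPair,
    sender: str,
    receiver: str,
    all_pairs: list[LRPair],
    network: SignalingNetwork,
    profiles: list[CellTypeProfile],
    params: ScoringParams,
    timepoint: str | None = None,
) -> float:
    """Loop strength for one forward pair at one timepoint.

    A reverse pair (L', R') from receiver back to sender qualifies when
    L' is among the downstream targets of the forward receptor in the
    receiver AND the forward ligand is among the downstream targets of
    R' in the sender.  The loop strength is the maximum reverse base
    score S0 over qualifying pairs (maximized over timepoints when no
    timepoint is given).
    """
    index = _ProfileIndex(profiles)
    t_fwd = downstream_targets(pair.receptor, network, params.K)
    best = 0.0
    tps = [timepoint] if timepoint is not None else index.timepoints
    for rev in all_pairs:
        if rev.ligand not in t_fwd:
            continue
        if pair.ligand not in downstream_targets(rev.receptor, network, params.K):
            continue
        for tp in tps:
            s0_rev, _ = _base_score(rev, receiver, sender, index, network, params, tp)
            best = max(best, s0_rev)
    return best


def _base_score(
    pair: LRPair,
    sender: str,
    receiver: str,
    index: _ProfileIndex,
    network: SignalingNetwork,
    params: ScoringParams,
    timepoint: str,
    support_cache: dict | None = None,
) -> tuple[float, tuple[float, float, float]]:
    e_l = index.scaled_expr(pair.ligand, sender, timepoint)
    e_r = index.scaled_expr(pair.receptor, receiver, timepoint)
    key = (pair.receptor, receiver, timepoint)
    if support_cache is not None and key in support_cache:
        n_sup = support_cache[key]
    else:
        prof = index.by_key.get((receiver, timepoint))
        n_sup = 0.0 if prof is None else network_support(pair.receptor, prof, network, params)
        if support_cache is not None:
            support_cache[key] = n_sup
    s0, _ = combine_score(e_l, e_r, n_sup, 0.0, params.alpha, params.gamma)
    return s0, (e_l, e_r, n_sup)


def score_interactions(
    profiles: list[CellTypeProfile],
    lr_db: list[LRPair],
    network: SignalingNetwork,
    params: ScoringParams = ScoringParams(),
    senders: list[str] | None = None,
    receivers: list[str] | None = None,
) -> pd.DataFrame:
    """Score every LR pair for all ordered (sender, receiver) group
    pairs, autocrine included, at every timepoint.

    Returns a frame with ``SCORE_COLUMNS``.  Pairs whose ligand or
    receptor is absent from the gene universe are skipped with a
    warning.
    """
    index = _ProfileIndex(profiles)
    senders = list(senders) if senders is not None else index.groups
    receivers = list(receivers) if receivers is not None else index.groups

    usable: list[LRPair] = []
    for pair in lr_db:
        if not (index.has_gene(pair.ligand) and index.has_gene(pair.receptor)):
            warnings.warn(
                f"skipping pair {pair.ligand}-{pair.receptor}: gene absent from profiles",
                stacklevel=2,
            )
            continue
        usable.append(pair)

    # Topological loop partners are timepoint-independent: precompute the
    # qualifying reverse-pair set per forward pair once.
    target_cache: dict[str, set[str]] = {}

    def targets(receptor: str) -> set[str]:
        if receptor not in target_cache:
            target_cache[receptor] = downstream_targets(receptor, network, params.K)
        return target_cache[receptor]

    loop_partners: dict[LRPair, list[LRPair]] = {}
    for pair in usable:
        t_fwd = targets(pair.receptor)
        loop_partners[pair] = [
            rev for rev in usable
            if rev.ligand in t_fwd and pair.ligand in targets(rev.receptor)
        ]

    support_cache: dict = {}
    base: dict[tuple[LRPair, str, str, str], tuple[float, tuple[float, float, float]]] = {}
    all_groups = sorted(set(senders) | set(receivers))
    for pair in usable:
        for s in all_groups:
            for r in all_groups:
                for tp in index.timepoints:
                    base[(pair, s, r, tp)] = _base_score(
                        pair, s, r, index, network, params, tp, support_cache
                    )

    rows = []
    for pair in usable:
        for s in senders:
            for r in receivers:
                for tp in index.timepoints:
                    s0, (e_l, e_r, n_sup) = base[(pair, s, r, tp)]
                    loop = 0.0
                    for rev in loop_partners[pair]:
                        loop = max(loop, base[(rev, r, s, tp)][0])
                    _, s_lr = combine_score(e_l, e_r, n_sup, loop, params.alpha, params.gamma)
                    rows.append((s, r, pair.ligand, pair.receptor, tp,
                                 e_l, e_r, n_sup, s0, loop, s_lr))
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


# ---------------------------------------------------------------------------
# filtering & aggregation
# ---------------------------------------------------------------------------

def filter_interactions(
    scores: pd.DataFrame,
    profiles: list[CellTypeProfile],
    params: ScoringParams = ScoringParams(),
) -> pd.DataFrame:
    """Apply the two retention criteria to a score table.

    A (sender, receiver, pair) triple is kept when (1) the ligand is
    detected in >= ``detection_min`` of sender cells and the receptor in
    >= ``detection_min`` of receiver cells at some timepoint, and (2)
    its S_LR reaches ``score_min`` (at one timepoint by default, at all
    timepoints with ``score_any_timepoint=False``).
    """
    index = _ProfileIndex(profiles)
    keep_keys = []
    for key, grp in scores.groupby(["sender", "receiver", "ligand", "receptor"], sort=False):
        sender, receiver, ligand, receptor = key
        det_l = max(index.detection(ligand, sender, tp) for tp in index.timepoints)
        det_r = max(index.detection(receptor, receiver, tp) for tp in index.timepoints)
        if det_l < params.detection_min or det_r < params.detection_min:
            continue
        s = grp["S_LR"]
        ok = (s.max() >= params.score_min) if params.score_any_timepoint else (s.min() >= params.score_min)
        if ok:
            keep_keys.append(key)
    if not keep_keys:
        return scores.iloc[0:0].copy()
    keyframe = scores.set_index(["sender", "receiver", "ligand", "receptor"])
    out = keyframe.loc[keep_keys].reset_index()
    return out[SCORE_COLUMNS]


def aggregate_celltype_scores(
    retained: pd.DataFrame,
    sender: str | None = None,
    receiver: str | None = None,
    per_timepoint: bool = False,
) -> pd.DataFrame | float:
    """Overall communication score between cell-type groups: the sum of
    retained S_LR values.

    With ``sender``/``receiver`` given, returns the scalar sum (per
    timepoint when requested, else summed across timepoints); otherwise
    a frame of sums for every (sender, receiver) present.
    """
    frame = retained
    if sender is not None:
        frame = frame[frame["sender"] == sender]
    if receiver is not None:
        frame = frame[frame["receiver"] == receiver]
    if sender is not None and receiver is not None:
        if per_timepoint:
            return frame.groupby("timepoint", sort=False)["S_LR"].sum().to_frame("overall_score").reset_index()
        return float(frame["S_LR"].sum())
    keys = ["sender", "receiver"] + (["timepoint"] if per_timepoint else [])
    return frame.groupby(keys, sort=False)["S_LR"].sum().to_frame("overall_score").reset_index()
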