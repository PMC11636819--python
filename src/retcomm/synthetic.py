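"""Synthetic multi-timepoint atlases with planted ground truth.

Generates labeled negative-binomial count matrices emulating an injured
retina: ~14 cell types, RGC subclasses split into high- and
low-survival classes, four timepoints, and planted ligand-receptor
interactions whose receptors are preferentially expressed by the
high-survival subclasses — either constantly ("preset") or only after
injury ("induced").  A companion network builder wires feedback loops
for planted pairs so the scoring stage's loop finder can recover them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import ExpressionAtlas, METADATA_COLUMNS
from .scoring import LRPair, SignalingNetwork

__all__ = [
    "SimDesign",
    "PlantedInteraction",
    "SyntheticTruth",
    "DesignError",
    "simulate_experiment",
    "build_synthetic_network",
    "design_mean_table",
    "lr_database",
    "export_truth",
    "load_truth",
    "default_design",
]

DEFAULT_TIMEPOINTS = ("control", "12h", "24h", "48h")


class DesignError(ValueError):
    """A simulation design violates one of its invariants."""


@dataclass
class PlantedInteraction:
    """One ground-truth interaction.

    The per-timepoint ``induction_schedule`` multiplies both the ligand
    boost (in the sender) and the receptor boost (in the target
    subclasses).  Preset interactions use a constant schedule; induced
    ones a schedule of 1.0 at control and > 1.0 afterwards.
    """

    ligand: str
    receptor: str
    sender: str
    target_subclasses: tuple[str, ...]
    pattern: str  # "preset" | "induced"
    ligand_boost: float = 8.0
    receptor_boost: float = 8.0
    induction_schedule: dict[str, float] = field(default_factory=dict)
    has_loop: bool = False
    loop_partner: tuple[str, str] | None = None

    def validate(self, design: "SimDesign") -> None:
        if self.sender not in design.cell_type_names():
            raise DesignError(f"planted sender {self.sender!r} is not a declared cell type")
        if not self.target_subclasses:
            raise DesignError(f"planted pair {self.ligand}-{self.receptor}: empty target_subclasses")
        subclasses = {name for name, _ in design.rgc_subclasses}
        unknown = set(self.target_subclasses) - subclasses
        if unknown:
            raise DesignError(f"unknown target subclass(es): {sorted(unknown)}")
        if self.pattern not in ("preset", "induced"):
            raise DesignError(f"pattern must be preset or induced, got {self.pattern!r}")
        sched = self.schedule_for(design.timepoints)
        if self.pattern == "induced":
            if sched[design.timepoints[0]] != 1.0:
                raise DesignError("induced pattern requires control multiplier 1.0")
            if not any(sched[t] > 1.0 for t in design.timepoints[1:]):
                raise DesignError("induced pattern requires a post-injury multiplier > 1.0")
        else:
            if len({sched[t] for t in design.timepoints}) != 1:
                raise DesignError("preset pattern requires identical multipliers at all timepoints")
        if min(self.ligand_boost, self.receptor_boost) < 1.0:
            raise DesignError("boosts must be >= 1")
        if self.has_loop and self.loop_partner is None:
            raise DesignError(f"pair {self.ligand}-{self.receptor}: has_loop needs a loop_partner")

    def schedule_for(self, timepoints: tuple[str, ...]) -> dict[str, float]:
        if self.induction_schedule:
            missing = set(timepoints) - set(self.induction_schedule)
            if missing:
                raise DesignError(f"induction_schedule missing timepoint(s): {sorted(missing)}")
            return dict(self.induction_schedule)
        return {t: 1.0 for t in timepoints}


@dataclass
class SimDesign:
    n_cell_types: int = 14
    rgc_subclasses: tuple[tuple[str, str], ...] = (
        ("ipRGC", "high"), ("aRGC", "high"), ("Gpr88RGC", "high"),
        ("T-RGC", "low"), ("N-RGC", "low"), ("W-RGC", "low"),
    )
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    cells_per_group: int = 100
    n_genes: int = 200
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 0.5
    nb_dispersion: float = 2.0
    marker_boost: float = 1.0
    planted: tuple[PlantedInteraction, ...] = ()
    n_decoys: int = 0
    decoy_ligand_boost: float = 8.0
    decoy_receptor_boost: float = 8.0
    loop_partner_boost: float = 4.0
    library_size_sd: float = 0.2
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.rgc_subclasses = tuple((str(n), str(c)) for n, c in self.rgc_subclasses)
        self.timepoints = tuple(self.timepoints)
        self.planted = tuple(self.planted)
        self.validate()

    def validate(self) -> None:
        classes = {c for _, c in self.rgc_subclasses}
        bad = classes - {"high", "low"}
        if bad:
            raise DesignError(f"survival_class must be high/low, got {sorted(bad)}")
        if "high" not in classes or "low" not in classes:
            raise DesignError("need at least one high- and one low-survival subclass")
        if len(self.timepoints) < 2:
            raise DesignError("need at least 2 timepoints")
        if self.timepoints[0] != "control":
            raise DesignError("first timepoint must be 'control'")
        if self.nb_dispersion <= 0:
            raise DesignError("nb_dispersion must be > 0")
        if self.marker_boost < 1.0:
            raise DesignError("marker_boost must be >= 1")
        if self.noise_sd < 0:
            raise DesignError("noise_sd must be >= 0")
        if self.n_cell_types < 2:
            raise DesignError("need >= 2 cell types (RGC plus at least one other)")
        for p in self.planted:
            p.validate(self)

    # -- naming conventions -------------------------------------------
    def cell_type_names(self) -> list[str]:
        return ["RGC"] + [f"ct{i:02d}" for i in range(1, self.n_cell_types)]

    def gene_names(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_genes)]

    def group_names(self) -> list[str]:
        """Sampling groups: non-RGC types plus each RGC subclass."""
        return self.cell_type_names()[1:] + [name for name, _ in self.rgc_subclasses]


@dataclass
class SyntheticTruth:
    planted: tuple[PlantedInteraction, ...]
    decoys: tuple[tuple[str, str, str], ...]  # (ligand, receptor, sender)
    design: SimDesign

    def __post_init__(self) -> None:
        planted_keys = {(p.ligand, p.receptor, p.sender) for p in self.planted}
        overlap = planted_keys & set(self.decoys)
        if overlap:
            raise DesignError(f"planted/decoy overlap: {sorted(overlap)}")


# ---------------------------------------------------------------------------
# design -> mean table
# ---------------------------------------------------------------------------

def _decoy_list(design: SimDesign) -> list[tuple[str, str, str]]:
    """Deterministic decoy assignment from the tail of the gene pool."""
    used = set()
    for p in design.planted:
        used.update((p.ligand, p.receptor))
        if p.loop_partner:
            used.update(p.loop_partner)
    pool = [g for g in reversed(design.gene_names()) if g not in used]
    need = 2 * design.n_decoys
    if len(pool) < need:
        raise DesignError(
            f"gene pool too small for {design.n_decoys} decoys ({len(pool)} free genes)"
        )
    senders = design.cell_type_names()[1:]
    decoys = []
    for i in range(design.n_decoys):
        ligand, receptor = pool[2 * i], pool[2 * i + 1]
        decoys.append((ligand, receptor, senders[i % len(senders)]))
    return decoys


def design_mean_table(design: SimDesign) -> dict[tuple[str, str], np.ndarray]:
    """Expected count mean per gene for every (group, timepoint).

    This is the exact quantity the sampler feeds the negative binomial
    (before per-cell library and noise factors, both of which have unit
    mean), so empirical group means converge to these values.
    """
    rng = np.random.default_rng(design.seed)
    genes = design.gene_names()
    gene_idx = {g: i for i, g in enumerate(genes)}
    baseline = rng.lognormal(design.baseline_log_mean, design.baseline_log_sd, size=design.n_genes)

    groups = design.group_names()
    subclass_of = {name: cls for name, cls in design.rgc_subclasses}
    means = {(g, t): baseline.copy() for g in groups for t in design.timepoints}

    # cell-type markers: a deterministic block of genes per group
    if design.marker_boost > 1.0:
        n_mark = max(1, design.n_genes // (4 * len(groups)))
        for gi, group in enumerate(groups):
            lo = (gi * n_mark) % design.n_genes
            rows = [(lo + j) % design.n_genes for j in range(n_mark)]
            for t in design.timepoints:
                means[(group, t)][rows] *= design.marker_boost

    def bump(gene: str, group: str, t: str, factor: float) -> None:
        means[(group, t)][gene_idx[gene]] *= factor

    for p in design.planted:
        sched = p.schedule_for(design.timepoints)
        for t in design.timepoints:
            bump(p.ligand, p.sender, t, p.ligand_boost * sched[t])
            for sub in p.target_subclasses:
                bump(p.receptor, sub, t, p.receptor_boost * sched[t])
            if p.has_loop and p.loop_partner:
                rev_l, rev_r = p.loop_partner
                for sub in p.target_subclasses:
                    bump(rev_l, sub, t, design.loop_partner_boost)
                bump(rev_r, p.sender, t, design.loop_partner_boost)

    rgc_subs = [name for name, _ in design.rgc_subclasses]
    for ligand, receptor, sender in _decoy_list(design):
        for t in design.timepoints:
            bump(ligand, sender, t, design.decoy_ligand_boost)
            for sub in rgc_subs:  # same level everywhere: no subclass bias
                bump(receptor, sub, t, design.decoy_receptor_boost)
    return means


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def simulate_experiment(design: SimDesign) -> tuple[ExpressionAtlas, SyntheticTruth]:
    """Draw a labeled count atlas from the design; deterministic in
    ``design.seed``."""
    design.validate()
    means = design_mean_table(design)
    # independent stream for sampling so mean-table construction stays
    # reusable without consuming the same draws
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 1]))

    subclass_of = {name: cls for name, cls in design.rgc_subclasses}
    groups = design.group_names()
    theta = design.nb_dispersion
    sigma = design.library_size_sd

    blocks: list[sp.csr_matrix] = []
    records = []
    for t in design.timepoints:
        for group in groups:
            mu = means[(group, t)][:, None]  # genes x 1
            n_cells = design.cells_per_group
            factors = np.ones(n_cells)
            if sigma > 0:
                factors = rng.lognormal(-0.5 * sigma**2, sigma, size=n_cells)
            cell_mu = mu * factors[None, :]
            if design.noise_sd > 0:
                cell_mu = cell_mu * rng.lognormal(
                    -0.5 * design.noise_sd**2, design.noise_sd, size=cell_mu.shape
                )
            p = theta / (theta + cell_mu)
            block = rng.negative_binomial(theta, p)
            blocks.append(sp.csr_matrix(block))
            is_rgc = group in subclass_of
            for i in range(n_cells):
                records.append(
                    (
                        f"{group}_{t}_{i:05d}",
                        "RGC" if is_rgc else group,
                        group if is_rgc else None,
                        subclass_of.get(group),
                        t,
                        f"{t}_rep1",
                    )
                )
    counts = sp.hstack(blocks, format="csr")
    cells = pd.DataFrame(records, columns=METADATA_COLUMNS)
    atlas = ExpressionAtlas(
        counts=counts, genes=design.gene_names(), cells=cells,
        timepoints=design.timepoints, rgc_type="RGC",
    )
    truth = SyntheticTruth(
        planted=design.planted, decoys=tuple(_decoy_list(design)), design=design
    )
    return atlas, truth


def lr_database(truth: SyntheticTruth) -> list[LRPair]:
    """All pairs the scorer should consider: planted pairs, their loop
    partners (reverse direction), and the decoys."""
    pairs: list[LRPair] = []
    seen = set()

    def add(l: str, r: str) -> None:
        if (l, r) not in seen:
            seen.add((l, r))
            pairs.append(LRPair(l, r))

    for p in truth.planted:
        add(p.ligand, p.receptor)
        if p.has_loop and p.loop_partner:
            add(*p.loop_partner)
    for ligand, receptor, _ in truth.decoys:
        add(ligand, receptor)
    return pairs


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

def build_synthetic_network(
    truth: SyntheticTruth,
    extra_edges: int = 0,
    seed: int = 0,
    n_targets: int = 4,
) -> SignalingNetwork:
    """Receptor -> TF -> target scaffolding for every pair, plus loop
    closure for planted pairs flagged ``has_loop`` and ``extra_edges``
    random distractor edges.

    Every receptor gets one signaling edge to a TF gene and regulatory
    edges from that TF onto ``n_targets`` shared baseline target genes,
    so the scorer's network support is well-defined for each pair.
    Receptors of looped pairs get a dedicated TF (the forward TF
    additionally regulates the reverse ligand and the reverse TF the
    forward ligand); all other receptors share one TF, which keeps the
    gene budget small and guarantees no receptor-to-ligand path exists
    outside the planted loops.
    """
    design = truth.design
    genes = design.gene_names()
    special = set()
    plain_receptors: list[str] = []
    looped_receptors: list[str] = []
    for p in truth.planted:
        special.update((p.ligand, p.receptor))
        if p.has_loop and p.loop_partner:
            special.update(p.loop_partner)
            looped_receptors += [p.receptor, p.loop_partner[1]]
        else:
            plain_receptors.append(p.receptor)
            if p.loop_partner:
                special.update(p.loop_partner)
                plain_receptors.append(p.loop_partner[1])
    for ligand, receptor, _ in truth.decoys:
        special.update((ligand, receptor))
        plain_receptors.append(receptor)
    looped_receptors = list(dict.fromkeys(looped_receptors))
    plain_receptors = [r for r in dict.fromkeys(plain_receptors) if r not in looped_receptors]

    free = [g for g in genes if g not in special]
    need = 1 + n_targets + len(looped_receptors)
    if len(free) < need:
        raise DesignError(f"gene pool too small for network scaffolding (need {need} free genes)")

    edges: list[tuple[str, str, str]] = []
    cursor = 0
    targets = []
    shared_tf = free[cursor]; cursor += 1
    for _ in range(n_targets):
        targets.append(free[cursor]); cursor += 1

    tf_of: dict[str, str] = {}
    for rec in looped_receptors:
        tf_of[rec] = free[cursor]; cursor += 1
    for rec in plain_receptors:
        tf_of[rec] = shared_tf

    for rec in plain_receptors + looped_receptors:
        edges.append((rec, tf_of[rec], "signaling"))
    for tf in dict.fromkeys(tf_of.values()):
        for tgt in targets:
            edges.append((tf, tgt, "regulatory"))

    for p in truth.planted:
        if p.has_loop and p.loop_partner:
            rev_l, rev_r = p.loop_partner
            edges.append((tf_of[p.receptor], rev_l, "regulatory"))
            edges.append((tf_of[rev_r], p.ligand, "regulatory"))

    if extra_edges:
        rng = np.random.default_rng(seed)
        existing = set(edges)
        while extra_edges > 0:
            src, dst = rng.choice(len(genes), size=2, replace=False)
            kind = "signaling" if rng.random() < 0.5 else "regulatory"
            e = (genes[src], genes[dst], kind)
            if e not in existing:
                existing.add(e)
                edges.append(e)
                extra_edges -= 1
    return SignalingNetwork(edges)


# ---------------------------------------------------------------------------
# truth round-trip
# ---------------------------------------------------------------------------

def export_truth(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "planted": [
            {**asdict(p),
             "target_subclasses": list(p.target_subclasses),
             "loop_partner": list(p.loop_partner) if p.loop_partner else None}
            for p in truth.planted
        ],
        "decoys": [list(d) for d in truth.decoys],
        "design": {
            **asdict(truth.design),
            "rgc_subclasses": [list(x) for x in truth.design.rgc_subclasses],
            "timepoints": list(truth.design.timepoints),
            "planted": None,  # stored once, at top level
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_truth(path: str | Path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    planted = tuple(
        PlantedInteraction(
            **{**d,
               "target_subclasses": tuple(d["target_subclasses"]),
               "loop_partner": tuple(d["loop_partner"]) if d["loop_partner"] else None}
        )
        for d in payload["planted"]
    )
    ddict = dict(payload["design"])
    ddict["rgc_subclasses"] = tuple(tuple(x) for x in ddict["rgc_subclasses"])
    ddict["timepoints"] = tuple(ddict["timepoints"])
    ddict["planted"] = planted
    design = SimDesign(**ddict)
    return SyntheticTruth(
        planted=planted,
        decoys=tuple(tuple(d) for d in payload["decoys"]),
        design=design,
    )


# ---------------------------------------------------------------------------
# convenience designs
# ---------------------------------------------------------------------------

def default_design(
    n_cell_types: int = 8,
    n_high: int = 2,
    n_low: int = 2,
    n_genes: int = 300,
    cells_per_group: int = 200,
    n_planted: int = 4,
    n_decoys: int = 10,
    n_loops: int = 0,
    receptor_boost: float = 8.0,
    seed: int = 0,
    **overrides,
) -> SimDesign:
    """A ready-made design with alternating preset/induced planted
    pairs targeting the high-survival subclasses.

    Gene ids for planted pairs are taken from the front of the pool
    (ligand and receptor, plus two loop-partner genes for looped
    pairs); decoys from the back.
    """
    highs = [("ipRGC", "high"), ("aRGC", "high"), ("Gpr88RGC", "high")][:n_high]
    while len(highs) < n_high:
        highs.append((f"hRGC{len(highs)}", "high"))
    lows = [("T-RGC", "low"), ("N-RGC", "low"), ("W-RGC", "low")][:n_low]
    while len(lows) < n_low:
        lows.append((f"lRGC{len(lows)}", "low"))
    subclasses = tuple(highs + lows)
    high_names = tuple(n for n, _ in highs)
    senders = [f"ct{i:02d}" for i in range(1, n_cell_types)]
    timepoints = DEFAULT_TIMEPOINTS

    planted = []
    cursor = 0
    for i in range(n_planted):
        has_loop = i < n_loops
        base = cursor
        cursor += 4 if has_loop else 2
        ligand, receptor = f"g{base:04d}", f"g{base + 1:04d}"
        induced = i % 2 == 1
        schedule = (
            {"control": 1.0, "12h": receptor_boost, "24h": receptor_boost, "48h": receptor_boost}
            if induced else {t: 1.0 for t in timepoints}
        )
        planted.append(
            PlantedInteraction(
                ligand=ligand,
                receptor=receptor,
                sender=senders[i % len(senders)],
                target_subclasses=high_names,
                pattern="induced" if induced else "preset",
                ligand_boost=receptor_boost if not induced else 1.0,
                receptor_boost=receptor_boost if not induced else 1.0,
                induction_schedule=schedule,
                has_loop=has_loop,
                loop_partner=(f"g{base + 2:04d}", f"g{base + 3:04d}") if has_loop else None,
            )
        )
    return SimDesign(
        n_cell_types=n_cell_types,
        rgc_subclasses=subclasses,
        cells_per_group=cells_per_group,
        n_genes=n_genes,
        planted=tuple(planted),
        n_decoys=n_decoys,
        decoy_receptor_boost=receptor_boost,
        seed=seed,
        **overrides,
    )
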