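"""Two-species developmental scRNA-seq simulator with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: two species sampled at discrete hpf time points, a branching
lineage tree with per-lineage proliferation, species-specific specification
delays, and regulator-target gene pairs whose co-expression is conserved,
temporally shifted, lost, or novel in the second species.

Expression model
----------------
Each gene has a baseline mean (gamma-distributed across genes, shared by
both species). Lineage identity adds marker-gene programs gated by a
logistic onset at the lineage's branch time; a set of "maturation" genes
with staggered onsets provides a continuous developmental-time axis. In
species B every lineage's effective developmental time is shifted by its
configured onset delay. Regulator-target interactions add a shared logistic
gate to both genes of the pair in one lineage; the four evolutionary
scenarios modify only the species-B copy of that gate.

Counts are negative-binomial (gamma-Poisson) around depth-scaled means,
with independent dropout; per-cell depth is lognormal around the configured
mean UMI total. A fixed seed makes every output byte-identical.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import CountMatrix, OrthologMap

ROOT = "root"

_STATUS_RE = re.compile(r"^(conserved|lost|novel|shifted:\+?(-?\d+(\.\d+)?)h?)$")


@dataclass
class Interaction:
    regulator: str
    target: str
    lineage: str
    onset_hpf: float
    status_in_B: str = "conserved"

    def __post_init__(self) -> None:
        if not _STATUS_RE.match(self.status_in_B):
            raise ValueError(
                f"bad interaction status {self.status_in_B!r}; expected "
                "conserved | lost | novel | shifted:+<hours>"
            )

    @property
    def shift_hours(self) -> float:
        if self.status_in_B.startswith("shifted:"):
            return float(self.status_in_B.split(":")[1].rstrip("h"))
        return 0.0


@dataclass
class SimConfig:
    """Study-design parameters for the two-species simulator.

    Defaults mirror the real sampling design: species A sampled hourly from
    2 to 24 hpf, species B at 6, 9, 12, 16, 20, 24 and 30 hpf, with a mean
    sequencing depth of ~2,500 UMIs per cell. Smaller, scenario-specific
    configurations for testing live in the ``*_scenario`` factories.
    """

    n_genes: int = 800
    lineage_tree: list[tuple[str, str, float]] = field(
        default_factory=lambda: [
            (ROOT, "ectoderm", 7.0),
            (ROOT, "mesendoderm", 7.0),
            ("mesendoderm", "endoderm", 10.0),
            ("mesendoderm", "mesoderm", 10.0),
        ]
    )
    timepoints_A: list[float] = field(default_factory=lambda: [float(t) for t in range(2, 25)])
    timepoints_B: list[float] = field(default_factory=lambda: [6.0, 9.0, 12.0, 16.0, 20.0, 24.0, 30.0])
    onset_delay_per_lineage_B: dict[str, float] = field(default_factory=dict)
    expected_cells_per_timepoint: dict[tuple[str, float], int] = field(default_factory=dict)
    interactions: list[Interaction] = field(default_factory=list)
    growth_rate_per_lineage: dict[str, float] = field(default_factory=dict)
    nb_dispersion: float = 2.0
    dropout_rate: float = 0.1
    mean_depth_umis: float = 2500.0
    depth_sigma: float = 0.35
    n_markers_per_lineage: int = 25
    n_maturation_genes: int = 40
    marker_strength: float = 10.0
    maturation_strength: float = 6.0
    interaction_strength: float = 8.0
    gate_steepness_h: float = 1.0
    default_growth_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.mean_depth_umis <= 0:
            raise ValueError("mean_depth_umis must be positive")
        for name in ("timepoints_A", "timepoints_B"):
            tps = getattr(self, name)
            if sorted(tps) != list(tps):
                raise ValueError(f"{name} must be sorted ascending")
        if not self.expected_cells_per_timepoint:
            self.expected_cells_per_timepoint = {
                **{("A", t): 2650 for t in self.timepoints_A},
                **{("B", t): 3300 for t in self.timepoints_B},
            }
        self.interactions = [
            i if isinstance(i, Interaction) else Interaction(*i)
            for i in self.interactions
        ]
        self._validate_tree()
        lineages = self.lineages()
        for inter in self.interactions:
            if inter.lineage not in lineages:
                raise ValueError(f"interaction lineage {inter.lineage!r} not in tree")
        for sp_name, tps in (("A", self.timepoints_A), ("B", self.timepoints_B)):
            for t in tps:
                n = self.expected_cells_per_timepoint.get((sp_name, t), 0)
                if n <= 0 and self.interactions:
                    raise ValueError(
                        f"zero cells at ({sp_name}, {t}) with interactions scheduled"
                    )

    def _validate_tree(self) -> None:
        branch_time = {ROOT: -np.inf}
        for parent, child, t in self.lineage_tree:
            if parent not in branch_time:
                raise ValueError(f"tree edge parent {parent!r} defined after child or missing")
            if t <= branch_time[parent]:
                raise ValueError("branch times must increase along root-to-leaf paths")
            branch_time[child] = t
        self._branch_time = branch_time
        self._children = {l: [] for l in branch_time}
        for parent, child, t in self.lineage_tree:
            self._children[parent].append(child)

    def lineages(self) -> list[str]:
        return list(self._branch_time)

    def growth_rate(self, lineage: str) -> float:
        return self.growth_rate_per_lineage.get(lineage, self.default_growth_rate)

    def delay_B(self, lineage: str) -> float:
        return self.onset_delay_per_lineage_B.get(lineage, 0.0)


@dataclass
class SimTruth:
    """Ground truth of a simulation run; the acceptance oracle."""

    cells: pd.DataFrame  # barcode, species, timepoint_hpf, lineage
    onsets: pd.DataFrame  # species, lineage, onset_hpf
    interactions: pd.DataFrame  # regulator, target, lineage, onset_hpf, status_in_B
    expected_cells: dict[tuple[str, float], int]
    growth_rates: dict[str, float]
    config: SimConfig


def _logistic(t: float, onset: float, steepness: float) -> float:
    return float(1.0 / (1.0 + np.exp(-(t - onset) / steepness)))


def active_lineages(cfg: SimConfig, t: float) -> list[str]:
    """Lineages a cell can carry at time t: branched on, not yet refined."""
    out = []
    for lin in cfg.lineages():
        if cfg._branch_time[lin] > t:
            continue
        kids = [c for c in cfg._children[lin] if cfg._branch_time[c] <= t]
        if not kids:
            out.append(lin)
    return out


def lineage_mass(cfg: SimConfig, lineage: str, t: float) -> float:
    """Unnormalized clone mass of a lineage at time t.

    Mass starts at 1 for the root, splits equally among children at each
    branch point, and grows exponentially at the lineage's growth rate.
    """
    path = [lineage]
    while path[-1] != ROOT:
        parent = next(p for p, c, _ in cfg.lineage_tree if c == path[-1])
        path.append(parent)
    path.reverse()
    mass = 1.0
    t0 = min(min(cfg.timepoints_A, default=0.0), min(cfg.timepoints_B, default=0.0))
    birth = t0
    for i, lin in enumerate(path):
        end = cfg._branch_time[path[i + 1]] if i + 1 < len(path) else t
        end = min(end, t)
        if end > birth:
            mass *= np.exp(cfg.growth_rate(lin) * (end - birth))
        if i + 1 < len(path):
            n_sibs = sum(
                1 for c in cfg._children[lin]
                if cfg._branch_time[c] == cfg._branch_time[path[i + 1]]
            )
            mass /= max(n_sibs, 1)
            birth = cfg._branch_time[path[i + 1]]
    return float(mass)


def lineage_proportions(cfg: SimConfig, t: float) -> dict[str, float]:
    lins = active_lineages(cfg, t)
    masses = np.array([lineage_mass(cfg, l, t) for l in lins])
    masses /= masses.sum()
    return dict(zip(lins, masses))


def _largest_remainder(n: int, proportions: np.ndarray) -> np.ndarray:
    """Deterministic integer partition of n by proportions."""
    raw = n * proportions
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def _ancestor_or_self(cfg: SimConfig, lineage: str, t: float) -> str:
    """The active label at time t on the path from root to `lineage`."""
    path = [lineage]
    while path[-1] != ROOT:
        parent = next(p for p, c, _ in cfg.lineage_tree if c == path[-1])
        path.append(parent)
    for lin in path:  # deepest first
        if cfg._branch_time[lin] <= t:
            return lin
    return ROOT


class _GeneModel:
    """Deterministic assignment of genes to baseline/marker/maturation roles."""

    def __init__(self, cfg: SimConfig):
        rng = np.random.default_rng([cfg.seed, 17])
        self.gene_ids = [f"g{i:04d}" for i in range(cfg.n_genes)]
        self.baseline = rng.gamma(shape=0.6, scale=2.0, size=cfg.n_genes) + 0.05
        # reserve interaction genes first so factories can name them freely;
        # regulated genes are silent outside their gated domains, which is
        # what makes absence of co-expression biologically readable
        reserved = {g for i in cfg.interactions for g in (i.regulator, i.target)}
        for g in reserved:
            if g not in self.gene_ids:
                raise ValueError(f"interaction gene {g!r} outside gene vocabulary")
        for g in reserved:
            self.baseline[self.gene_ids.index(g)] = 0.0
        # every interaction's target (and regulator, when a spare lineage
        # exists) gets a second expression domain in another lineage so a
        # lost interaction leaves both genes individually expressed
        non_root = [l for l in cfg.lineages() if l != ROOT]
        self.alt_domains: list[tuple[str | None, str | None]] = []
        for inter in cfg.interactions:
            others = [l for l in non_root if l != inter.lineage]
            tgt_alt = others[0] if others else None
            reg_alt = others[1] if len(others) > 1 else None
            self.alt_domains.append((tgt_alt, reg_alt))
        free = [i for i, g in enumerate(self.gene_ids) if g not in reserved]
        rng.shuffle(free)
        pos = 0
        self.markers: dict[str, np.ndarray] = {}
        lineages = [l for l in cfg.lineages() if l != ROOT]
        for lin in lineages:
            k = min(cfg.n_markers_per_lineage, max(0, (len(free) - pos)))
            self.markers[lin] = np.array(free[pos:pos + k], dtype=int)
            pos += k
        k = min(cfg.n_maturation_genes, max(0, len(free) - pos))
        mat_idx = np.array(free[pos:pos + k], dtype=int)
        self.maturation_idx = mat_idx
        # staggered onsets across the sampled window
        all_t = list(cfg.timepoints_A) + list(cfg.timepoints_B)
        lo, hi = (min(all_t), max(all_t)) if all_t else (0.0, 1.0)
        self.maturation_onsets = np.linspace(lo, hi, max(len(mat_idx), 1))
        self.gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    def mean_vector(self, cfg: SimConfig, species: str, lineage: str,
                    t: float) -> np.ndarray:
        """Expected relative expression for one (species, lineage, time) group."""
        mu = self.baseline.copy()
        delay = cfg.delay_B(lineage) if species == "B" else 0.0
        tau = t - delay
        s = cfg.gate_steepness_h
        # lineage programs: every branch on the root->lineage path contributes
        path = [lineage]
        while path[-1] != ROOT:
            parent = next(p for p, c, _ in cfg.lineage_tree if c == path[-1])
            path.append(parent)
        for lin in path:
            if lin == ROOT or lin not in self.markers:
                continue
            gate = _logistic(tau, cfg._branch_time[lin], s)
            mu[self.markers[lin]] += cfg.marker_strength * gate
        for gi, onset in zip(self.maturation_idx, self.maturation_onsets):
            mu[gi] += cfg.maturation_strength * _logistic(tau, onset, 2.0 * s)
        for inter, (tgt_alt, reg_alt) in zip(cfg.interactions, self.alt_domains):
            r = self.gene_index[inter.regulator]
            g = self.gene_index[inter.target]
            # second expression domains, identical in both species
            if tgt_alt is not None and tgt_alt in path:
                mu[g] += cfg.interaction_strength * _logistic(t, inter.onset_hpf, s)
            if reg_alt is not None and reg_alt in path:
                mu[r] += cfg.interaction_strength * _logistic(t, inter.onset_hpf, s)
            # the interaction itself acts in the designated lineage + descendants
            if inter.lineage not in path:
                continue
            if species == "A":
                if inter.status_in_B == "novel":
                    continue
                gate = _logistic(t, inter.onset_hpf, s)
                mu[r] += cfg.interaction_strength * gate
                mu[g] += cfg.interaction_strength * gate
            else:
                if inter.status_in_B == "lost":
                    gate = _logistic(t, inter.onset_hpf, s)
                    mu[r] += cfg.interaction_strength * gate  # regulator kept
                else:
                    onset = inter.onset_hpf + inter.shift_hours
                    gate = _logistic(t, onset, s)
                    mu[r] += cfg.interaction_strength * gate
                    mu[g] += cfg.interaction_strength * gate
        return mu


def simulate_two_species(cfg: SimConfig):
    """Run the generator.

    Returns ``(matrices_A, matrices_B, cell_table, ortholog_map, truth)``
    where ``matrices_A``/``matrices_B`` map timepoint -> CountMatrix.
    """
    rng = np.random.default_rng([cfg.seed, 29])
    model = _GeneModel(cfg)
    mats: dict[str, dict[float, CountMatrix]] = {"A": {}, "B": {}}
    truth_rows = []
    for species, tps in (("A", cfg.timepoints_A), ("B", cfg.timepoints_B)):
        for t in tps:
            n = cfg.expected_cells_per_timepoint.get((species, t), 0)
            props = lineage_proportions(cfg, t)
            lins = list(props)
            counts_per_lin = _largest_remainder(n, np.array([props[l] for l in lins]))
            blocks = []
            barcodes = []
            for lin, k in zip(lins, counts_per_lin):
                if k == 0:
                    continue
                mu = model.mean_vector(cfg, species, lin, t)
                p = mu / mu.sum()
                log_mu = np.log(cfg.mean_depth_umis) - 0.5 * cfg.depth_sigma ** 2
                depth = rng.lognormal(log_mu, cfg.depth_sigma, size=k)
                lam = depth[:, None] * p[None, :]
                if np.isfinite(cfg.nb_dispersion):
                    theta = cfg.nb_dispersion
                    lam = rng.gamma(theta, lam / theta)
                x = rng.poisson(lam)
                if cfg.dropout_rate > 0:
                    keep = rng.random(x.shape) >= cfg.dropout_rate
                    x = x * keep
                blocks.append(sp.csc_matrix(x.T))
                start = len(barcodes)
                bcs = [f"{species}_t{t:g}_c{start + j:05d}" for j in range(k)]
                barcodes.extend(bcs)
                for b in bcs:
                    truth_rows.append((b, species, t, lin))
            counts = sp.hstack(blocks).tocsc() if blocks else sp.csc_matrix(
                (cfg.n_genes, 0), dtype=np.int64)
            mats[species][t] = CountMatrix(
                counts.astype(np.int64), list(model.gene_ids), barcodes,
                species=species, timepoint_hpf=float(t))
    cells = pd.DataFrame(truth_rows, columns=["barcode", "species",
                                              "timepoint_hpf", "lineage"])
    onsets = pd.DataFrame(
        [
            (species, lin,
             cfg._branch_time[lin] + (cfg.delay_B(lin) if species == "B" else 0.0))
            for species in ("A", "B")
            for lin in cfg.lineages() if lin != ROOT
        ],
        columns=["species", "lineage", "onset_hpf"],
    )
    inter_df = pd.DataFrame(
        [(i.regulator, i.target, i.lineage, i.onset_hpf, i.status_in_B)
         for i in cfg.interactions],
        columns=["regulator", "target", "lineage", "onset_hpf", "status_in_B"],
    )
    truth = SimTruth(cells=cells, onsets=onsets, interactions=inter_df,
                     expected_cells=dict(cfg.expected_cells_per_timepoint),
                     growth_rates={l: cfg.growth_rate(l) for l in cfg.lineages()},
                     config=cfg)
    om = OrthologMap([(g, g) for g in model.gene_ids])
    cell_table = _truth_cell_table(mats, cells)
    return mats["A"], mats["B"], cell_table, om, truth


def _truth_cell_table(mats, cells: pd.DataFrame) -> pd.DataFrame:
    from .io_formats import make_cell_table

    all_mats = list(mats["A"].values()) + list(mats["B"].values())
    tbl = make_cell_table(all_mats)
    return tbl.merge(cells[["barcode", "lineage"]], on="barcode", how="left")


def truth_lineage_tree(truth: SimTruth, species: str = "A"):
    """True lineage transition graph per consecutive time point pair.

    Nodes are (lineage, timepoint); an edge carries the fraction of the
    parent clone's descendants that carry each child label one time point
    later, computed from the clone-mass model (outgoing weights sum to 1).
    """
    from .fate_views import LineageGraph, LineageNode, LineageEdge

    cfg = truth.config
    tps = cfg.timepoints_A if species == "A" else cfg.timepoints_B
    counts = truth.cells.query("species == @species").groupby(
        ["timepoint_hpf", "lineage"]).size()
    nodes, edges = [], []
    for t in tps:
        for lin in active_lineages(cfg, t):
            n = int(counts.get((t, lin), 0))
            nodes.append(LineageNode(f"{lin}@{t:g}", lin, float(t), n))
    for t_prev, t_next in zip(tps[:-1], tps[1:]):
        for lin in active_lineages(cfg, t_prev):
            descendants = [
                d for d in active_lineages(cfg, t_next)
                if _ancestor_or_self(cfg, d, t_prev) == lin
            ]
            masses = np.array([lineage_mass(cfg, d, t_next) for d in descendants])
            weights = masses / masses.sum()
            for d, w in zip(descendants, weights):
                edges.append(LineageEdge(f"{lin}@{t_prev:g}", f"{d}@{t_next:g}",
                                         float(w)))
    return LineageGraph(nodes=nodes, edges=edges)


# --- scenario factories (test-scale study designs) --------------------------


def tree_scenario(seed: int = 1, cells_per_timepoint: int = 300) -> SimConfig:
    """Three terminal lineages over five time points, ~300 cells each."""
    tps = [6.0, 9.0, 12.0, 15.0, 18.0]
    return SimConfig(
        n_genes=400,
        lineage_tree=[
            (ROOT, "ectoderm", 7.0),
            (ROOT, "mesendoderm", 7.0),
            ("mesendoderm", "endoderm", 10.0),
            ("mesendoderm", "mesoderm", 10.0),
        ],
        timepoints_A=tps,
        timepoints_B=tps,
        expected_cells_per_timepoint={
            **{("A", t): cells_per_timepoint for t in tps},
            **{("B", t): cells_per_timepoint for t in tps},
        },
        mean_depth_umis=2500.0,
        seed=seed,
    )


def alignment_scenario(seed: int = 1, delay_h: float = 3.0,
                       cells_per_timepoint: int = 250) -> SimConfig:
    """Four terminal lineages; species B delayed globally by `delay_h` hours.

    Species B is sampled one extra interval past species A's window (as the
    real sampling design did for the slower species) so the delayed final
    states are actually observed.
    """
    tps = [6.0, 9.0, 12.0, 15.0, 18.0, 21.0]
    tps_b = tps + [24.0]
    tree = [
        (ROOT, "ectoderm", 7.0),
        (ROOT, "mesendoderm", 7.0),
        ("mesendoderm", "endoderm", 9.5),
        ("mesendoderm", "mesoderm", 9.5),
        ("mesoderm", "pigment", 12.5),
        ("mesoderm", "skeletogenic", 12.5),
    ]
    lineages = {p for p, _, _ in tree} | {c for _, c, _ in tree}
    return SimConfig(
        n_genes=400,
        lineage_tree=tree,
        timepoints_A=tps,
        timepoints_B=tps_b,
        onset_delay_per_lineage_B={l: delay_h for l in lineages},
        expected_cells_per_timepoint={
            **{("A", t): cells_per_timepoint for t in tps},
            **{("B", t): cells_per_timepoint for t in tps_b},
        },
        seed=seed,
    )


def interaction_scenario(seed: int = 1, cells_per_timepoint: int = 500) -> SimConfig:
    """Injected conserved / lost / shifted(+6 h) regulator-target pairs."""
    tps = [6.0, 9.0, 12.0, 15.0, 18.0, 21.0, 24.0]
    inter = []
    gi = 300
    for k in range(4):
        inter.append(Interaction(f"g{gi:04d}", f"g{gi + 1:04d}", "mesoderm",
                                 9.0, "conserved"))
        gi += 2
    for k in range(4):
        inter.append(Interaction(f"g{gi:04d}", f"g{gi + 1:04d}", "mesoderm",
                                 9.0, "lost"))
        gi += 2
    for k in range(4):
        inter.append(Interaction(f"g{gi:04d}", f"g{gi + 1:04d}", "mesoderm",
                                 9.0, "shifted:+6h"))
        gi += 2
    return SimConfig(
        n_genes=400,
        lineage_tree=[
            (ROOT, "ectoderm", 7.0),
            (ROOT, "mesoderm", 7.0),
        ],
        timepoints_A=tps,
        timepoints_B=tps,
        interactions=inter,
        expected_cells_per_timepoint={
            **{("A", t): cells_per_timepoint for t in tps},
            **{("B", t): cells_per_timepoint for t in tps},
        },
        seed=seed,
    )
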