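"""End-to-end orchestration: simulate -> QC -> embed -> cluster -> transport ->
fates -> trees/triangles -> ortholog restriction -> alignment -> co-expression.

The stage functions are plain library calls shared by the CLI, the tests and
the acceptance script; `run_pipeline` strings them together from a YAML
config and records a manifest.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic_data as synth
from .coexpression import (CoexpressionParams, classify_interaction,
                           coexpression_timecourse)
from .cross_species import align_timecourses, joint_embedding_cca, restrict_to_orthologs
from .fate_views import (build_lineage_graph, graph_edge_f1,
                         map_clusters_to_lineages, triangle_projection)
from .io_formats import CountMatrix, PipelineConfig, write_10x_mtx, write_lineage_graph
from .preprocess import cluster_cells, embed_pca, filter_cells, normalize_log_cpm, select_variable_genes
from .transport import fate_probabilities, learn_growth

SCENARIOS = {
    "tree": synth.tree_scenario,
    "alignment": synth.alignment_scenario,
    "interaction": synth.interaction_scenario,
}


@dataclass
class RunManifest:
    config: dict
    config_checksum: str
    seed: int
    stages: dict = field(default_factory=dict)  # name -> {status, outputs, warnings}
    outputs: list = field(default_factory=list)

    def record(self, stage: str, status: str, outputs: list[str],
               warnings_: list[str] | None = None) -> None:
        self.stages[stage] = {
            "status": status,
            "outputs": outputs,
            "warnings": warnings_ or [],
        }
        self.outputs.extend(outputs)

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


@dataclass
class SpeciesAnalysis:
    """Per-species intermediate results threaded through the stages."""

    matrices: dict[float, CountMatrix]
    cell_table: pd.DataFrame
    merged: CountMatrix | None = None
    norm: np.ndarray | None = None
    embedding_by_t: dict[float, np.ndarray] | None = None
    barcodes_by_t: dict[float, list[str]] | None = None
    clusters: pd.DataFrame | None = None
    growth: object = None
    maps: list | None = None


def preprocess_species(matrices: dict[float, CountMatrix],
                       cfg: PipelineConfig, do_filter: bool = True
                       ) -> SpeciesAnalysis:
    """QC, normalization, HVG selection, PCA and clustering for one species."""
    filtered = {}
    for t, cm in matrices.items():
        filtered[t] = (filter_cells(cm, cfg.min_genes, cfg.max_genes,
                                    cfg.max_counts) if do_filter else cm)
    merged = _concat_matrices(list(filtered.values()))
    norm = normalize_log_cpm(merged)
    hvg = select_variable_genes(norm, min(cfg.n_hvg, norm.shape[0]),
                                merged.gene_ids)
    emb = embed_pca(norm[hvg, :], min(cfg.n_pcs, len(hvg), merged.n_cells),
                    barcodes=merged.barcodes)
    labels = cluster_cells(emb, min(cfg.k_neighbors, merged.n_cells - 1),
                           cfg.cluster_resolution, cfg.seed)
    times = merged.timepoints()
    clusters = pd.DataFrame({
        "barcode": merged.barcodes,
        "timepoint_hpf": times,
        "cluster": [str(c) for c in labels],
    })
    emb_by_t, bc_by_t = {}, {}
    for t in sorted(filtered):
        m = times == t
        emb_by_t[t] = emb.coords[m]
        bc_by_t[t] = [b for b, keep in zip(merged.barcodes, m) if keep]
    return SpeciesAnalysis(matrices=filtered, cell_table=merged.cell_stats(),
                           merged=merged, norm=norm, embedding_by_t=emb_by_t,
                           barcodes_by_t=bc_by_t, clusters=clusters)


def _concat_matrices(mats: list[CountMatrix]) -> CountMatrix:
    import scipy.sparse as sp

    gene_ids = mats[0].gene_ids
    for m in mats:
        if m.gene_ids != gene_ids:
            raise ValueError("matrices must share one gene vocabulary")
    counts = sp.hstack([m.counts for m in mats]).tocsc()
    barcodes = [b for m in mats for b in m.barcodes]
    times = np.concatenate([m.timepoints() for m in mats])
    return CountMatrix(counts, gene_ids, barcodes,
                       species=mats[0].species, timepoint_hpf=times)


def transport_species(sa: SpeciesAnalysis, expected_totals: dict[float, float],
                      cfg: PipelineConfig):
    """Growth-rate learning and transport maps over all interval pairs."""
    growth, maps = learn_growth(
        sa.embedding_by_t, expected_totals,
        epsilon=cfg.epsilon, lambda1=cfg.lambda1, lambda2=cfg.lambda2,
        n_iter=cfg.growth_iters, barcodes=sa.barcodes_by_t)
    sa.growth = growth
    sa.maps = maps
    return growth, maps


def fate_sets_from_annotations(annotations: pd.DataFrame, barcodes_at_ref: list[str],
                               label_col: str = "lineage") -> dict[str, np.ndarray]:
    """Fate sets at the reference timepoint from a cell-annotation table."""
    lut = annotations.set_index("barcode")[label_col]
    labels = lut.reindex(barcodes_at_ref)
    out = {}
    for lab in sorted(labels.dropna().unique()):
        out[str(lab)] = np.flatnonzero((labels == lab).to_numpy())
    return out


def species_fates(sa: SpeciesAnalysis, annotations: pd.DataFrame,
                  from_t: float, label_col: str = "lineage"):
    """Fate probabilities for cells at from_t toward the species' final
    timepoint cell types."""
    ref_t = max(sa.embedding_by_t)
    fate_sets = fate_sets_from_annotations(annotations,
                                           sa.barcodes_by_t[ref_t], label_col)
    return fate_probabilities(sa.maps, fate_sets, from_t, ref_t,
                              barcodes=sa.barcodes_by_t[from_t])


def all_timepoint_fates(sa: SpeciesAnalysis, annotations: pd.DataFrame,
                        label_col: str = "lineage"):
    """Stacked fate matrix over every timepoint (cells ordered by time)."""
    from .transport import FateMatrix

    ref_t = max(sa.embedding_by_t)
    mats = []
    barcodes = []
    times = []
    fate_names = None
    for t in sorted(sa.embedding_by_t):
        fm = species_fates(sa, annotations, t, label_col)
        fate_names = fm.fate_names
        mats.append(fm.probs)
        barcodes.extend(fm.barcodes)
        times.extend([t] * len(fm.barcodes))
    stacked = FateMatrix(probs=np.vstack(mats), fate_names=fate_names,
                         reference_timepoint=ref_t, barcodes=barcodes)
    return stacked, np.array(times)


def run_pipeline(config_path: str | Path, outdir: str | Path | None = None,
                 seed: int | None = None) -> RunManifest:
    """Execute the configured stages; returns (and writes) the run manifest."""
    config_path = Path(config_path)
    with open(config_path) as fh:
        conf = yaml.safe_load(fh) or {}
    _validate_config(conf)
    if seed is not None:
        conf["seed"] = int(seed)
    outdir = Path(outdir or conf.get("outdir", "evodevo_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    checksum = hashlib.sha256(config_path.read_bytes()).hexdigest()
    manifest = RunManifest(config=conf, config_checksum=checksum,
                           seed=int(conf.get("seed", 0)))
    stages = conf.get("stages", ["simulate", "preprocess", "transport",
                                 "fates", "tree", "align", "coexpr", "report"])
    params = conf.get("params", {})
    cfg = PipelineConfig(**{**params, "seed": int(conf.get("seed", 0))})
    state: dict = {"cfg": cfg}
    runner = {
        "simulate": _stage_simulate,
        "preprocess": _stage_preprocess,
        "transport": _stage_transport,
        "fates": _stage_fates,
        "tree": _stage_tree,
        "align": _stage_align,
        "coexpr": _stage_coexpr,
        "report": _stage_report,
    }
    for stage in stages:
        if stage not in runner:
            raise ValueError(f"unknown stage {stage!r}")
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                outputs = runner[stage](conf, state, outdir)
            manifest.record(stage, "ok", outputs,
                            [str(w.message) for w in caught])
        except Exception as exc:  # record partial completion, then re-raise
            manifest.record(stage, f"failed: {exc}", [])
            manifest.write(outdir / "manifest.json")
            raise
    manifest.write(outdir / "manifest.json")
    return manifest


_REQUIRED_PARAM_TYPES = {
    "epsilon": (int, float), "lambda1": (int, float), "lambda2": (int, float),
    "min_genes": int, "max_genes": int, "max_counts": int,
    "growth_iters": int, "fate_threshold": (int, float),
}


def _validate_config(conf: dict) -> None:
    if not isinstance(conf, dict):
        raise ValueError("config must be a mapping")
    scenario = conf.get("scenario", "tree")
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; "
                         f"choose from {sorted(SCENARIOS)}")
    params = conf.get("params", {})
    if "epsilon" not in params:
        raise ValueError("config missing required param 'epsilon'")
    for key, val in params.items():
        if key in _REQUIRED_PARAM_TYPES and not isinstance(
                val, _REQUIRED_PARAM_TYPES[key]):
            raise ValueError(f"config param {key!r} has wrong type")
    for key in conf.get("require_params", []):
        if key not in params:
            raise ValueError(f"config missing required param {key!r}")


def _stage_simulate(conf, state, outdir: Path) -> list[str]:
    scenario = conf.get("scenario", "tree")
    seed = int(conf.get("seed", 0))
    kwargs = conf.get("scenario_args", {})
    sim_cfg = SCENARIOS[scenario](seed=seed, **kwargs)
    mats_a, mats_b, cell_table, om, truth = synth.simulate_two_species(sim_cfg)
    state.update(mats_a=mats_a, mats_b=mats_b, cell_table=cell_table,
                 om=om, truth=truth, sim_cfg=sim_cfg)
    outputs = []
    if conf.get("write_counts", False):
        for species, mats in (("A", mats_a), ("B", mats_b)):
            for t, cm in mats.items():
                d = outdir / "counts" / f"{species}_t{t:g}"
                write_10x_mtx(cm, d)
                outputs.append(str(d))
    truth_path = outdir / "truth_cells.csv"
    truth.cells.to_csv(truth_path, index=False)
    outputs.append(str(truth_path))
    return outputs


def _stage_preprocess(conf, state, outdir: Path) -> list[str]:
    cfg = state["cfg"]
    outputs = []
    for species, key in (("A", "mats_a"), ("B", "mats_b")):
        sa = preprocess_species(state[key], cfg)
        state[f"sa_{species}"] = sa
        path = outdir / f"clusters_{species}.csv"
        sa.clusters.to_csv(path, index=False)
        outputs.append(str(path))
    return outputs


def _stage_transport(conf, state, outdir: Path) -> list[str]:
    cfg = state["cfg"]
    sim_cfg = state["sim_cfg"]
    outputs = []
    for species in ("A", "B"):
        sa = state[f"sa_{species}"]
        totals = {t: float(sim_cfg.expected_cells_per_timepoint[(species, t)])
                  for t in sa.embedding_by_t}
        growth, _ = transport_species(sa, totals, cfg)
        rows = [(t, g.mean(), g.min(), g.max()) for t, g in sorted(growth.g.items())]
        path = outdir / f"growth_{species}.csv"
        pd.DataFrame(rows, columns=["timepoint_hpf", "g_mean", "g_min",
                                    "g_max"]).to_csv(path, index=False)
        outputs.append(str(path))
    return outputs


def _stage_fates(conf, state, outdir: Path) -> list[str]:
    outputs = []
    annotations = state["truth"].cells
    for species in ("A", "B"):
        sa = state[f"sa_{species}"]
        fates, times = all_timepoint_fates(sa, annotations)
        state[f"fates_{species}"] = fates
        state[f"fate_times_{species}"] = times
        df = pd.DataFrame(fates.probs, columns=fates.fate_names)
        df.insert(0, "barcode", fates.barcodes)
        df.insert(1, "timepoint_hpf", times)
        path = outdir / f"fates_{species}.csv"
        df.to_csv(path, index=False)
        outputs.append(str(path))
        # triangle projection for the first two fates
        if len(fates.fate_names) >= 2:
            tri = triangle_projection(fates, fates.fate_names[0],
                                      fates.fate_names[1],
                                      state["cfg"].fate_threshold)
            tri_df = pd.DataFrame([t.__dict__ for t in tri])
            tri_df["timepoint_hpf"] = times
            tri_path = outdir / f"triangle_{species}.csv"
            tri_df.to_csv(tri_path, index=False)
            state[f"triangle_{species}"] = tri_df
            outputs.append(str(tri_path))
    return outputs


def _stage_tree(conf, state, outdir: Path) -> list[str]:
    cfg = state["cfg"]
    outputs = []
    for species in ("A", "B"):
        sa = state[f"sa_{species}"]
        graph = build_lineage_graph(sa.maps, sa.clusters,
                                    min_cells=cfg.tree_min_cells,
                                    edge_cutoff=cfg.tree_edge_cutoff)
        path = outdir / f"lineage_tree_{species}.json"
        write_lineage_graph(graph, path)
        outputs.append(str(path))
        truth_graph = synth.truth_lineage_tree(state["truth"], species)
        mapping = map_clusters_to_lineages(sa.clusters, state["truth"].cells)
        f1 = graph_edge_f1(graph, truth_graph, mapping)
        state[f"tree_f1_{species}"] = f1
    f1_path = outdir / "tree_edge_f1.json"
    with open(f1_path, "w") as fh:
        json.dump({sp: state[f"tree_f1_{sp}"] for sp in ("A", "B")}, fh)
    outputs.append(str(f1_path))
    return outputs


def _stage_align(conf, state, outdir: Path) -> list[str]:
    cfg = state["cfg"]
    sa_a, sa_b = state["sa_A"], state["sa_B"]
    cm_a = sa_a.merged
    cm_b = sa_b.merged
    ra, rb = restrict_to_orthologs(cm_a, cm_b, state["om"])
    na = normalize_log_cpm(ra)
    nb = normalize_log_cpm(rb)
    emb_a, emb_b = joint_embedding_cca(na, nb, k=min(cfg.n_pcs, na.shape[0]))
    fates_a, times_a = state["fates_A"], state["fate_times_A"]
    fates_b, times_b = state["fates_B"], state["fate_times_B"]
    shared = [f for f in fates_a.fate_names if f in fates_b.fate_names]
    lineage_fate_map = {f: (f, f) for f in shared}
    results = align_timecourses(emb_a.coords, times_a, emb_b.coords, times_b,
                                fates_a, fates_b, lineage_fate_map,
                                max_points=cfg.emd_max_points, seed=cfg.seed)
    state["alignment"] = results
    outputs = []
    rows = []
    for res in results:
        emd_path = outdir / f"emd_{res.cell_lineage}.csv"
        pd.DataFrame(res.emd, index=res.timepoints_A,
                     columns=res.timepoints_B).to_csv(emd_path)
        outputs.append(str(emd_path))
        for t, s in res.best_pairs:
            rows.append((res.cell_lineage, t, s))
    bp_path = outdir / "best_pairs.csv"
    pd.DataFrame(rows, columns=["lineage", "t_A", "t_B"]).to_csv(bp_path,
                                                                 index=False)
    outputs.append(str(bp_path))
    return outputs


def _stage_coexpr(conf, state, outdir: Path) -> list[str]:
    truth = state["truth"]
    if truth.interactions.empty:
        return []
    params = CoexpressionParams()
    mats_a = state["sa_A"].matrices
    mats_b = state["sa_B"].matrices
    b_to_a = state["om"].b_to_a()
    rows = []
    curves = []
    for _, row in truth.interactions.iterrows():
        prof_a = coexpression_timecourse(mats_a, row.regulator, row.target, "A")
        reg_b = next((b for a, b in state["om"].pairs if a == row.regulator),
                     row.regulator)
        tgt_b = next((b for a, b in state["om"].pairs if a == row.target),
                     row.target)
        prof_b = coexpression_timecourse(mats_b, reg_b, tgt_b, "B")
        call = classify_interaction(prof_a, prof_b, params,
                                    matrices_a=mats_a, matrices_b=mats_b)
        rows.append((row.regulator, row.target, row.status_in_B, call.label,
                     call.onset_A, call.onset_B,
                     call.peak_prop_A, call.peak_prop_B))
        for prof in (prof_a, prof_b):
            c = prof.table.copy()
            c.insert(0, "species", prof.species)
            c.insert(0, "pair", f"{row.regulator}-{row.target}")
            curves.append(c)
    summary = pd.DataFrame(rows, columns=["regulator", "target", "true_status",
                                          "called_label", "onset_A", "onset_B",
                                          "peak_prop_A", "peak_prop_B"])
    path = outdir / "interaction_calls.csv"
    summary.to_csv(path, index=False)
    curve_path = outdir / "coexpression_timecourses.csv"
    pd.concat(curves, ignore_index=True).to_csv(curve_path, index=False)
    state["interaction_calls"] = summary
    return [str(path), str(curve_path)]


def _stage_report(conf, state, outdir: Path) -> list[str]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    report_dir = outdir / "report"
    report_dir.mkdir(exist_ok=True)
    outputs = []
    if "alignment" in state:
        fig, ax = plt.subplots(figsize=(4, 4))
        for res in state["alignment"]:
            if res.best_pairs:
                t, s = zip(*res.best_pairs)
                ax.plot(t, s, marker="o", label=res.cell_lineage)
        lims = ax.get_xlim()
        ax.plot(lims, lims, "k--", lw=0.8, label="slope 1")
        ax.set_xlabel("species A time (hpf)")
        ax.set_ylabel("best-matching species B time (hpf)")
        ax.legend(fontsize=6)
        p = report_dir / "alignment.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        outputs.append(str(p))
    for species in ("A", "B"):
        key = f"triangle_{species}"
        if key in state:
            df = state[key]
            fig, ax = plt.subplots(figsize=(4, 4))
            colors = {"A": "tab:red", "B": "tab:purple", "other": "tab:gray",
                      "uncommitted": "lightgray"}
            for lab, grp in df.groupby("committed_to"):
                ax.scatter(grp["x"], grp["y"], s=3,
                           c=colors.get(lab, "k"), label=lab)
            ax.legend(fontsize=6)
            ax.set_aspect("equal")
            p = report_dir / f"triangle_{species}.png"
            fig.savefig(p, dpi=120, bbox_inches="tight")
            plt.close(fig)
            outputs.append(str(p))
    if "interaction_calls" in state:
        curves = pd.read_csv(outdir / "coexpression_timecourses.csv")
        fig, axes = plt.subplots(1, 1, figsize=(5, 3.5))
        for (pair, species), grp in curves.groupby(["pair", "species"]):
            color = "tab:green" if species == "A" else "tab:orange"
            axes.plot(grp["timepoint_hpf"], grp["proportion"], color=color,
                      alpha=0.5, lw=0.8)
        axes.set_xlabel("hpf")
        axes.set_ylabel("proportion of co-expressing cells")  # linear y axis
        p = report_dir / "coexpression_timecourses.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        outputs.append(str(p))
        summary_path = report_dir / "interaction_summary.csv"
        state["interaction_calls"].to_csv(summary_path, index=False)
        outputs.append(str(summary_path))
    return outputs
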