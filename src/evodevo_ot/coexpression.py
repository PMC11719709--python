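"""Cell-level regulator-target co-expression and its evolutionary classification.

Two genes are co-expressed in a cell when each has at least one UMI there —
always counted on raw UMIs, never normalized values. Cells split into a
"low" class (at least one of the two genes at exactly 1 UMI) and a
"moderate-to-high" class (both genes at >= 2 UMIs). Per-time-point
proportions of co-expressing cells form the time courses compared between
species, and a configurable decision cascade assigns each regulator-target
pair one of the evolutionary labels: conserved, temporally or spatially
shifted, lost, novel, or indeterminate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CountMatrix


@dataclass
class CoexpressionParams:
    """Thresholds of the interaction-evolution decision cascade.

    The published criteria are verbal; these defaults encode them ("a single
    stray low co-expressing cell is likely not functionally significant")
    and are exposed rather than canonical.
    """

    min_expressing_cells: int = 20
    max_stray_low_cells: int = 2
    min_signal_prop: float = 0.005
    min_high_cells: int = 5
    min_shift_hours: float = 4.0
    min_cluster_overlap: float = 0.5
    sustain_timepoints: int = 2  # onset needs this many consecutive signals
    onset_peak_fraction: float = 0.5  # half-maximum (t50) onset definition


@dataclass
class CoexpressionProfile:
    """Per-time-point co-expression counts for one gene pair in one species."""

    regulator: str
    target: str
    species: str
    table: pd.DataFrame  # timepoint_hpf, n_total_cells, n_coexpressing, n_low, n_high, proportion
    regulator_present: bool = True
    target_present: bool = True

    def proportions(self) -> pd.Series:
        return self.table.set_index("timepoint_hpf")["proportion"]


@dataclass
class InteractionCall:
    regulator: str
    target: str
    label: str  # conserved | shifted_temporal | shifted_spatial | lost | novel | indeterminate
    onset_A: float | None = None
    onset_B: float | None = None
    peak_prop_A: float = 0.0
    peak_prop_B: float = 0.0
    cluster_overlap: float | None = None
    support_A: tuple[bool, bool] = (True, True)  # regulator, target expressed
    support_B: tuple[bool, bool] = (True, True)
    notes: str = ""


def classify_cell_coexpression(umis_a: int, umis_b: int) -> str:
    """'none' if either gene is absent, 'high' if both have >= 2 UMIs,
    otherwise 'low' (at least one gene at exactly 1 UMI)."""
    if umis_a < 0 or umis_b < 0:
        raise ValueError("UMI counts must be nonnegative")
    if umis_a == 0 or umis_b == 0:
        return "none"
    if umis_a >= 2 and umis_b >= 2:
        return "high"
    return "low"


def _gene_row(cm: CountMatrix, gene: str) -> np.ndarray | None:
    try:
        i = cm.gene_ids.index(gene)
    except ValueError:
        return None
    return np.asarray(cm.counts[i, :].todense()).ravel()


def coexpression_timecourse(matrices: dict[float, CountMatrix], regulator: str,
                            target: str, species: str = "") -> CoexpressionProfile:
    """Tally co-expressing cells per time point, split into low/high classes."""
    rows = []
    reg_present = True
    tgt_present = True
    for t in sorted(matrices):
        cm = matrices[t]
        if cm.n_cells == 0:
            raise ValueError(f"timepoint {t} has no cells")
        r = _gene_row(cm, regulator)
        g = _gene_row(cm, target)
        if r is None:
            reg_present = False
        if g is None:
            tgt_present = False
        if r is None or g is None:
            rows.append((t, cm.n_cells, 0, 0, 0, 0.0))
            continue
        both = (r >= 1) & (g >= 1)
        high = (r >= 2) & (g >= 2)
        n_co = int(both.sum())
        n_high = int(high.sum())
        rows.append((t, cm.n_cells, n_co, n_co - n_high, n_high,
                     n_co / cm.n_cells))
    if not reg_present or not tgt_present:
        warnings.warn(
            f"gene(s) missing from matrices: "
            f"{'' if reg_present else regulator} {'' if tgt_present else target}"
        )
    table = pd.DataFrame(rows, columns=["timepoint_hpf", "n_total_cells",
                                        "n_coexpressing", "n_low", "n_high",
                                        "proportion"])
    if not species and matrices:
        species = next(iter(matrices.values())).species
    return CoexpressionProfile(regulator, target, species, table,
                               regulator_present=reg_present,
                               target_present=tgt_present)


def coexpression_overlay(matrices: dict[float, CountMatrix], regulator: str,
                         target: str, coords: pd.DataFrame,
                         clusters: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-cell co-expression class joined to 2-D plot coordinates.

    ``coords`` needs columns barcode, x, y. Returns one row per cell with
    class in {none, low, high} for the three-tone overlay plots.
    """
    recs = []
    for t in sorted(matrices):
        cm = matrices[t]
        r = _gene_row(cm, regulator)
        g = _gene_row(cm, target)
        for i, bc in enumerate(cm.barcodes):
            ra = 0 if r is None else int(r[i])
            ga = 0 if g is None else int(g[i])
            recs.append((bc, t, classify_cell_coexpression(ra, ga)))
    df = pd.DataFrame(recs, columns=["barcode", "timepoint_hpf", "class"])
    merged = df.merge(coords[["barcode", "x", "y"]], on="barcode", how="left")
    missing = merged.loc[merged["x"].isna(), "barcode"].tolist()
    if missing:
        raise ValueError(f"missing coordinates for barcodes: {missing[:5]}"
                         f"{'...' if len(missing) > 5 else ''}")
    if clusters is not None:
        merged = merged.merge(clusters[["barcode", "cluster"]], on="barcode",
                              how="left")
    return merged


def _expression_support(matrices: dict[float, CountMatrix], gene: str,
                        min_cells: int) -> bool:
    total = 0
    for cm in matrices.values():
        row = _gene_row(cm, gene)
        if row is not None:
            total += int((row >= 1).sum())
        if total >= min_cells:
            return True
    return total >= min_cells


def _onset(profile: CoexpressionProfile, params: CoexpressionParams) -> float | None:
    """Half-maximum (t50) onset: earliest timepoint whose proportion reaches
    onset_peak_fraction of the pair's peak (floored by min_signal_prop),
    sustained over the required consecutive timepoints. The relative
    threshold makes onset calls robust to how strong the pair's signal is."""
    tab = profile.table
    peak = float(tab["proportion"].max())
    thresh = max(params.min_signal_prop, params.onset_peak_fraction * peak)
    ok = (tab["proportion"] >= thresh).to_numpy()
    need = params.sustain_timepoints
    for i in range(len(ok) - need + 1):
        if ok[i:i + need].all():
            return float(tab["timepoint_hpf"].iloc[i])
    return None


def _has_signal(profile: CoexpressionProfile, params: CoexpressionParams) -> bool:
    tab = profile.table
    return bool(((tab["proportion"] >= params.min_signal_prop)
                 & (tab["n_high"] >= params.min_high_cells)).any())


def _is_absent(profile: CoexpressionProfile, params: CoexpressionParams) -> bool:
    tab = profile.table
    return (int(tab["n_high"].sum()) == 0
            and int(tab["n_coexpressing"].sum()) <= params.max_stray_low_cells)


def majority_cluster(profile_matrices: dict[float, CountMatrix], regulator: str,
                     target: str, clusters: pd.DataFrame) -> str | None:
    """Cluster containing the plurality of co-expressing cells."""
    lut = clusters.set_index("barcode")["cluster"]
    votes: dict[str, int] = {}
    for cm in profile_matrices.values():
        r = _gene_row(cm, regulator)
        g = _gene_row(cm, target)
        if r is None or g is None:
            continue
        for i in np.flatnonzero((r >= 1) & (g >= 1)):
            c = lut.get(cm.barcodes[i])
            if c is not None:
                votes[c] = votes.get(c, 0) + 1
    if not votes:
        return None
    return max(sorted(votes), key=lambda c: votes[c])


def classify_interaction(profile_a: CoexpressionProfile,
                         profile_b: CoexpressionProfile,
                         params: CoexpressionParams | None = None,
                         matrices_a: dict[float, CountMatrix] | None = None,
                         matrices_b: dict[float, CountMatrix] | None = None,
                         clusters_a: pd.DataFrame | None = None,
                         clusters_b: pd.DataFrame | None = None,
                         homologous_cluster_map: dict[str, str] | None = None
                         ) -> InteractionCall:
    """Decision cascade for the evolutionary status of one interaction.

    1. expression support: each gene needs >= min_expressing_cells cells
       with >= 1 UMI somewhere in its species, else indeterminate;
    2. lost: species B shows no moderate-to-high cells and at most a stray
       handful of low cells while A has a supported signal;
    3. novel: the mirror image;
    4. shifted_temporal: both onsets detected and differing by at least
       min_shift_hours;
    5. shifted_spatial: the majority co-expressing cluster in B is not
       homologous to A's;
    6. conserved otherwise.
    """
    params = params or CoexpressionParams()
    call = InteractionCall(profile_a.regulator, profile_a.target, "conserved")
    if matrices_a is not None:
        call.support_A = (
            _expression_support(matrices_a, profile_a.regulator,
                                params.min_expressing_cells),
            _expression_support(matrices_a, profile_a.target,
                                params.min_expressing_cells),
        )
    if matrices_b is not None:
        call.support_B = (
            _expression_support(matrices_b, profile_b.regulator,
                                params.min_expressing_cells),
            _expression_support(matrices_b, profile_b.target,
                                params.min_expressing_cells),
        )
    call.peak_prop_A = float(profile_a.table["proportion"].max())
    call.peak_prop_B = float(profile_b.table["proportion"].max())
    if not all(call.support_A) or not all(call.support_B):
        call.label = "indeterminate"
        call.notes = "a gene lacks expression support in one species"
        return call
    signal_a = _has_signal(profile_a, params)
    signal_b = _has_signal(profile_b, params)
    if signal_a and _is_absent(profile_b, params):
        call.label = "lost"
        call.onset_A = _onset(profile_a, params)
        return call
    if signal_b and _is_absent(profile_a, params):
        call.label = "novel"
        call.onset_B = _onset(profile_b, params)
        return call
    call.onset_A = _onset(profile_a, params)
    call.onset_B = _onset(profile_b, params)
    if (call.onset_A is not None and call.onset_B is not None
            and abs(call.onset_A - call.onset_B) >= params.min_shift_hours):
        call.label = "shifted_temporal"
        return call
    if (matrices_a is not None and matrices_b is not None
            and clusters_a is not None and clusters_b is not None):
        if homologous_cluster_map is None:
            call.notes = "spatial test skipped: no homologous cluster map"
        else:
            maj_a = majority_cluster(matrices_a, profile_a.regulator,
                                     profile_a.target, clusters_a)
            maj_b = majority_cluster(matrices_b, profile_b.regulator,
                                     profile_b.target, clusters_b)
            if maj_a is not None and maj_b is not None:
                overlap = 1.0 if homologous_cluster_map.get(maj_a) == maj_b else 0.0
                call.cluster_overlap = overlap
                if overlap < params.min_cluster_overlap:
                    call.label = "shifted_spatial"
                    return call
    call.label = "conserved"
    return call
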