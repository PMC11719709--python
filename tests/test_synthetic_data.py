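import numpy as np
import pytest

from evodevo_ot.synthetic_data import (ROOT, Interaction, SimConfig,
                                       active_lineages, lineage_proportions,
                                       simulate_two_species, tree_scenario,
                                       truth_lineage_tree)


def _single_lineage_cfg(**kw):
    defaults = dict(
        n_genes=5,
        lineage_tree=[],
        timepoints_A=[6.0],
        timepoints_B=[6.0],
        expected_cells_per_timepoint={("A", 6.0): 1000, ("B", 6.0): 10},
        nb_dispersion=np.inf,
        dropout_rate=0.0,
        depth_sigma=0.0,
        mean_depth_umis=200.0,
        n_markers_per_lineage=0,
        n_maturation_genes=0,
        seed=3,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def test_poisson_limit_mean_matches_configuration():
    """With no dispersion, dropout or depth spread, per-gene count means hit
    the configured depth-scaled expectation within 3 standard errors."""
    cfg = _single_lineage_cfg()
    mats_a, _, _, _, truth = simulate_two_species(cfg)
    cm = mats_a[6.0]
    from evodevo_ot.synthetic_data import _GeneModel

    model = _GeneModel(cfg)
    mu = model.mean_vector(cfg, "A", ROOT, 6.0)
    expected = cfg.mean_depth_umis * mu / mu.sum()
    x = cm.counts.toarray()
    for g in range(cfg.n_genes):
        se = np.sqrt(expected[g] / x.shape[1])  # Poisson SE of the mean
        assert abs(x[g].mean() - expected[g]) < 3 * se + 1e-9


def test_determinism_under_fixed_seed():
    cfg1 = tree_scenario(seed=5, cells_per_timepoint=60)
    cfg2 = tree_scenario(seed=5, cells_per_timepoint=60)
    a1, b1, t1, _, tr1 = simulate_two_species(cfg1)
    a2, b2, t2, _, tr2 = simulate_two_species(cfg2)
    for t in a1:
        assert (a1[t].counts != a2[t].counts).nnz == 0
        assert a1[t].barcodes == a2[t].barcodes
    for t in b1:
        assert (b1[t].counts != b2[t].counts).nnz == 0
    assert tr1.cells.equals(tr2.cells)


def test_different_seeds_differ():
    a1, _, _, _, _ = simulate_two_species(tree_scenario(seed=1, cells_per_timepoint=60))
    a2, _, _, _, _ = simulate_two_species(tree_scenario(seed=2, cells_per_timepoint=60))
    assert (a1[6.0].counts != a2[6.0].counts).nnz > 0


def test_negative_binomial_mean_variance_relation():
    """Sampled counts follow var = m + m^2/theta within Monte-Carlo slack."""
    theta = 2.0
    cfg = _single_lineage_cfg(nb_dispersion=theta, n_genes=3,
                              expected_cells_per_timepoint={("A", 6.0): 5000,
                                                            ("B", 6.0): 10},
                              seed=11)
    mats_a, _, _, _, _ = simulate_two_species(cfg)
    x = mats_a[6.0].counts.toarray()
    for g in range(3):
        m = x[g].mean()
        v = x[g].var()
        expected_v = m + m * m / theta
        assert v == pytest.approx(expected_v, rel=0.15)


def test_lost_interaction_cooccurrence_at_background_rate():
    """A lost target keeps no expression in the interaction lineage, so B's
    regulator-target co-occurrence cannot exceed the analytic independence
    rate implied by the configured (zero) baseline."""
    inter = Interaction("g0003", "g0004", "meso", 8.0, "lost")
    cfg = SimConfig(
        n_genes=6,
        lineage_tree=[(ROOT, "ecto", 5.0), (ROOT, "meso", 5.0)],
        timepoints_A=[12.0], timepoints_B=[12.0],
        expected_cells_per_timepoint={("A", 12.0): 5000, ("B", 12.0): 10000},
        interactions=[inter],
        nb_dispersion=np.inf, dropout_rate=0.0,
        n_markers_per_lineage=0, n_maturation_genes=0,
        mean_depth_umis=300.0, seed=7,
    )
    _, mats_b, _, _, truth = simulate_two_species(cfg)
    cm = mats_b[12.0]
    r = np.asarray(cm.counts[cm.gene_ids.index("g0003")].todense()).ravel()
    t = np.asarray(cm.counts[cm.gene_ids.index("g0004")].todense()).ravel()
    meso = truth.cells.query("species == 'B'").set_index("barcode").loc[
        cm.barcodes, "lineage"].to_numpy() == "meso"
    # regulator stays active in meso; target has zero baseline there
    assert r[meso].sum() > 0
    assert int(((r >= 1) & (t >= 1) & meso).sum()) == 0


def test_onset_delay_shifts_marker_curves():
    """A species-B delay of d hours shifts the lineage marker mean-expression
    curve by d (cross-correlation argmax within one timepoint spacing)."""
    from evodevo_ot.synthetic_data import _GeneModel, alignment_scenario

    delay = 3.0
    cfg = alignment_scenario(seed=2, delay_h=delay, cells_per_timepoint=80)
    mats_a, mats_b, _, _, _ = simulate_two_species(cfg)
    model = _GeneModel(cfg)
    markers = model.markers["mesoderm"]

    def curve(mats, tps):
        vals = []
        for t in tps:
            x = mats[t].counts.toarray()
            depth = x.sum(axis=0)
            vals.append((x[markers, :] / np.maximum(depth, 1)).mean())
        return np.array(vals)

    tps = cfg.timepoints_A
    ca = curve(mats_a, tps)
    cb = curve(mats_b, tps)
    # best lag aligning B to A (B should look like A shifted later)
    lags = range(0, 3)
    scores = [np.corrcoef(ca[: len(tps) - l], cb[l:])[0, 1] for l in lags]
    best_lag_hours = 3.0 * int(np.argmax(scores))
    assert abs(best_lag_hours - delay) <= 3.0


def test_cell_counts_follow_expected_partition():
    cfg = tree_scenario(seed=1, cells_per_timepoint=300)
    mats_a, _, _, _, truth = simulate_two_species(cfg)
    for t, cm in mats_a.items():
        assert cm.n_cells == 300
        props = lineage_proportions(cfg, t)
        counts = truth.cells.query("species == 'A' and timepoint_hpf == @t")[
            "lineage"].value_counts()
        for lin, p in props.items():
            assert counts.get(lin, 0) == pytest.approx(300 * p, abs=1.0)


def test_truth_tree_single_lineage_is_path():
    cfg = _single_lineage_cfg(timepoints_A=[6.0, 9.0, 12.0],
                              expected_cells_per_timepoint={
                                  ("A", 6.0): 10, ("A", 9.0): 10,
                                  ("A", 12.0): 10, ("B", 6.0): 10})
    _, _, _, _, truth = simulate_two_species(cfg)
    g = truth_lineage_tree(truth, "A")
    assert len(g.nodes) == 3
    assert len(g.edges) == 2
    assert all(e.weight == pytest.approx(1.0) for e in g.edges)


def test_truth_tree_outgoing_weights_sum_to_one():
    cfg = tree_scenario(seed=1, cells_per_timepoint=50)
    _, _, _, _, truth = simulate_two_species(cfg)
    g = truth_lineage_tree(truth, "A")
    out = {}
    for e in g.edges:
        out.setdefault(e.parent, 0.0)
        out[e.parent] += e.weight
    assert out  # branching produced edges
    for total in out.values():
        assert total == pytest.approx(1.0, abs=1e-8)
    # the branch node has two outgoing edges
    root_out = [e for e in g.edges if e.parent == "root@6"]
    assert len(root_out) == 2


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="status"):
        Interaction("a", "b", "l", 6.0, "gone")
    with pytest.raises(ValueError, match="sorted"):
        SimConfig(timepoints_A=[9.0, 6.0])
    with pytest.raises(ValueError, match="lineage"):
        SimConfig(interactions=[Interaction("g0001", "g0002", "nope", 6.0)])
    with pytest.raises(ValueError, match="zero cells"):
        SimConfig(
            interactions=[Interaction("g0001", "g0002", "mesoderm", 6.0)],
            expected_cells_per_timepoint={("A", t): 0 for t in range(2, 25)},
        )


def test_active_lineages_respect_branch_times():
    cfg = tree_scenario(seed=1)
    assert active_lineages(cfg, 6.0) == [ROOT]
    assert set(active_lineages(cfg, 9.0)) == {"ectoderm", "mesendoderm"}
    assert set(active_lineages(cfg, 12.0)) == {"ectoderm", "endoderm", "mesoderm"}
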