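import numpy as np
import pytest

from evodevo_ot.transport import (TransportMap, compose_maps, cost_matrix,
                                  fate_probabilities, learn_growth,
                                  solve_unbalanced_ot, uot_objective)

from _oracles import balanced_sinkhorn, uot_dual_oracle


def test_cost_matrix_closed_forms():
    assert cost_matrix(np.array([[0.0]]), np.array([[0.0]])) == pytest.approx(0.0)
    c = cost_matrix(np.array([[0.0]]), np.array([[0.0], [2.0]]))
    # squared distances (0, 4), median nonzero = 4
    assert np.allclose(c, [[0.0, 1.0]])


def test_cost_matrix_matches_double_loop(rng):
    x = rng.normal(size=(7, 3))
    y = rng.normal(size=(5, 3))
    c = cost_matrix(x, y)
    brute = np.zeros((7, 5))
    for i in range(7):
        for j in range(5):
            brute[i, j] = ((x[i] - y[j]) ** 2).sum()
    brute /= np.median(brute[brute > 0])
    assert np.abs(c - brute).max() <= 1e-12


def test_cost_matrix_empty_slice_rejected():
    with pytest.raises(ValueError):
        cost_matrix(np.empty((0, 3)), np.ones((2, 3)))


def test_single_atom_coupling_conserves_mass():
    tm = solve_unbalanced_ot(np.array([[0.0]]), np.array([1.0]),
                             np.array([1.0]), epsilon=0.05,
                             lambda1=100.0, lambda2=100.0)
    assert tm.gamma == pytest.approx(np.array([[1.0]]), abs=1e-10)


def test_balanced_limit_matches_independent_sinkhorn(rng):
    """lambda -> infinity recovers balanced entropic transport."""
    C = rng.random((3, 3))
    C /= np.median(C[C > 0])
    a = np.full(3, 1 / 3)
    b = np.full(3, 1 / 3)
    tm = solve_unbalanced_ot(C, a, b, 0.05, 1e6, 1e6, max_iter=50000,
                             tol=1e-13)
    oracle = balanced_sinkhorn(C, a, b, 0.05)
    assert np.abs(tm.gamma - oracle).max() <= 1e-4


def test_solution_beats_random_couplings_and_matches_dual_oracle(rng):
    C = rng.random((4, 5))
    C /= np.median(C[C > 0])
    a = rng.random(4) + 0.2
    b = rng.random(5) + 0.2
    tm = solve_unbalanced_ot(C, a, b, 0.05, 1.0, 50.0, max_iter=20000,
                             tol=1e-12)
    mine = uot_objective(tm.gamma, C, a, b, 0.05, 1.0, 50.0)
    for _ in range(1000):
        g = rng.random((4, 5)) * 0.5
        assert mine <= uot_objective(g, C, a, b, 0.05, 1.0, 50.0) + 1e-9
    oracle = uot_dual_oracle(C, a, b, 0.05, 1.0, 50.0)
    assert abs(mine - uot_objective(oracle, C, a, b, 0.05, 1.0, 50.0)) <= 1e-6


def test_objective_decreases_across_scaling_iterations(rng):
    """Partial solves at increasing iteration counts do not increase the
    objective, across the stated epsilon range."""
    C = rng.random((6, 6))
    C /= np.median(C[C > 0])
    a = rng.random(6) + 0.1
    b = rng.random(6) + 0.1
    for eps in (0.01, 0.05, 0.2, 1.0):
        vals = []
        for iters in (1, 3, 10, 50, 300):
            tm = solve_unbalanced_ot(C, a, b, eps, 1.0, 50.0,
                                     max_iter=iters, tol=0.0)
            vals.append(uot_objective(tm.gamma, C, a, b, eps, 1.0, 50.0))
        assert all(v2 <= v1 + 1e-9 for v1, v2 in zip(vals, vals[1:]))


def test_kernel_underflow_raises():
    with pytest.raises(ValueError, match="rescale|epsilon"):
        solve_unbalanced_ot(np.array([[1e6, 1e6]]), np.array([1.0]),
                            np.array([0.5, 0.5]), epsilon=0.01)


def test_nonconvergence_warns_but_returns():
    rng = np.random.default_rng(1)
    C = rng.random((4, 4))
    with pytest.warns(UserWarning, match="converge"):
        tm = solve_unbalanced_ot(C, rng.random(4) + 0.1, rng.random(4) + 0.1,
                                 0.05, 1.0, 50.0, max_iter=2)
    assert not tm.converged


def test_growth_symmetric_fixture_near_one():
    """Equal expected totals on an exchange-symmetric fixture (100 points on
    a circle, so every cell is equivalent) learn g ~ 1 everywhere."""
    theta = np.linspace(0, 2 * np.pi, 100, endpoint=False)
    pts = np.column_stack([np.cos(theta), np.sin(theta)])
    embeddings = {0.0: pts, 1.0: pts.copy()}
    model, maps = learn_growth(embeddings, {0.0: 100.0, 1.0: 100.0},
                               n_iter=20)
    assert np.abs(model.g[0.0] - 1.0).max() <= 0.05


def test_growth_single_source_cell_exact():
    emb = {0.0: np.zeros((1, 2)), 3.0: np.random.default_rng(0).normal(size=(4, 2))}
    model, maps = learn_growth(emb, {0.0: 10.0, 3.0: 25.0}, n_iter=3)
    assert model.g[0.0][0] ** 3.0 == pytest.approx(2.5, abs=1e-9)


def test_growth_detects_faster_proliferating_lineage():
    """A lineage with doubled growth rate earns higher learned g in >= 95%
    of seeded replicates."""
    from evodevo_ot.io_formats import PipelineConfig
    from evodevo_ot.pipeline import preprocess_species, transport_species
    from evodevo_ot.synthetic_data import ROOT, SimConfig, simulate_two_species

    wins = 0
    n_rep = 20
    for seed in range(n_rep):
        cfg = SimConfig(
            n_genes=120,
            lineage_tree=[(ROOT, "fast", 3.0), (ROOT, "slow", 3.0)],
            timepoints_A=[6.0, 9.0], timepoints_B=[6.0],
            growth_rate_per_lineage={"fast": 0.3, "slow": 0.15},
            expected_cells_per_timepoint={("A", 6.0): 120, ("A", 9.0): 150,
                                          ("B", 6.0): 10},
            n_markers_per_lineage=20, seed=100 + seed,
        )
        mats_a, _, _, _, truth = simulate_two_species(cfg)
        pc = PipelineConfig(seed=seed, n_pcs=10)
        sa = preprocess_species(mats_a, pc, do_filter=False)
        n6 = 120 * np.exp(0.3 * 3) / 2 + 120 * np.exp(0.15 * 3) / 2
        transport_species(sa, {6.0: 120.0, 9.0: float(n6)}, pc)
        lut = truth.cells.set_index("barcode")["lineage"]
        lin = lut.reindex(sa.barcodes_by_t[6.0]).to_numpy()
        g = sa.growth.g[6.0]
        if g[lin == "fast"].mean() > g[lin == "slow"].mean():
            wins += 1
    assert wins >= int(0.95 * n_rep)


def _permutation_map(perm, t0, t1):
    n = len(perm)
    gamma = np.zeros((n, n))
    gamma[np.arange(n), perm] = 1.0
    return TransportMap(gamma, 0.05, 1.0, 50.0, t0, t1)


def test_compose_identity_permutation():
    tm = _permutation_map([0, 1, 2], 0.0, 1.0)
    M, zero = compose_maps([tm], 0.0, 1.0)
    assert np.allclose(M, np.eye(3))
    assert not zero.any()


def test_compose_matches_matrix_product(rng):
    g1 = rng.random((4, 5))
    g2 = rng.random((5, 3))
    maps = [TransportMap(g1, 0.05, 1, 50, 0.0, 1.0),
            TransportMap(g2, 0.05, 1, 50, 1.0, 2.0)]
    M, _ = compose_maps(maps, 0.0, 2.0)
    brute = (g1 / g1.sum(1, keepdims=True)) @ (g2 / g2.sum(1, keepdims=True))
    assert np.abs(M - brute).max() <= 1e-12
    assert np.abs(M.sum(1) - 1.0).max() <= 1e-8


def test_compose_gap_rejected(rng):
    maps = [TransportMap(rng.random((3, 3)), 0.05, 1, 50, 0.0, 1.0),
            TransportMap(rng.random((3, 3)), 0.05, 1, 50, 2.0, 3.0)]
    with pytest.raises(ValueError, match="chain"):
        compose_maps(maps, 0.0, 3.0)


def test_fate_probabilities_identity_transport():
    tm = _permutation_map([0, 1, 2], 0.0, 1.0)
    fm = fate_probabilities([tm], {"F": np.array([1]),
                                   "G": np.array([0, 2])}, 0.0, 1.0)
    assert fm.probs[1, 0] == pytest.approx(1.0)
    assert np.abs(fm.probs.sum(1) - 1.0).max() <= 1e-8


def test_fate_probabilities_symmetric_pull(rng):
    """Two equidistant fates attract a symmetric source equally."""
    src = np.zeros((1, 1))
    tgt = np.array([[1.0], [-1.0]])
    C = cost_matrix(src, tgt)
    tm = solve_unbalanced_ot(C, np.array([1.0]), np.array([0.5, 0.5]),
                             0.05, 1.0, 50.0)
    fm = fate_probabilities([tm], {"up": np.array([0]), "down": np.array([1])},
                            tm.source_timepoint, tm.target_timepoint)
    assert fm.probs[0] == pytest.approx([0.5, 0.5], abs=1e-6)


def test_fate_probabilities_empty_fate_set_rejected():
    tm = _permutation_map([0, 1], 0.0, 1.0)
    with pytest.raises(ValueError, match="empty"):
        fate_probabilities([tm], {"F": np.array([], dtype=int)}, 0.0, 1.0)


def test_fate_argmax_recovers_true_lineage(tree_run):
    """At the first fully-branched timepoint, the highest-probability fate
    matches the cell's true lineage for >= 90% of cells."""
    from evodevo_ot.pipeline import species_fates

    sa = tree_run["sa"]
    truth = tree_run["truth"]
    fm = species_fates(sa, truth.cells, 12.0)
    lut = truth.cells.set_index("barcode")["lineage"]
    true_lin = lut.reindex(fm.barcodes).to_numpy()
    pred = np.array(fm.fate_names)[fm.probs.argmax(axis=1)]
    assert (pred == true_lin).mean() >= 0.9


def test_markov_composition_consistency(tree_run):
    """Fate probabilities via t -> T equal t -> t' -> T composition."""
    sa = tree_run["sa"]
    maps = sa.maps
    M_direct, _ = compose_maps(maps, 9.0, 18.0)
    M_a, _ = compose_maps(maps, 9.0, 12.0)
    M_b, _ = compose_maps(maps, 12.0, 18.0)
    assert np.abs(M_direct - M_a @ M_b).max() <= 1e-10
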