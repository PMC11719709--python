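import numpy as np
import pytest
import scipy.sparse as sp

from evodevo_ot.cross_species import (align_timecourses, emd,
                                      joint_embedding_cca,
                                      restrict_to_orthologs)
from evodevo_ot.io_formats import CountMatrix, OrthologMap
from evodevo_ot.transport import FateMatrix

from _oracles import emd_assignment_oracle, emd_dual_lp


def _cm(arr, prefix="g", species="A"):
    arr = np.asarray(arr)
    return CountMatrix(sp.csc_matrix(arr),
                       [f"{prefix}{i}" for i in range(arr.shape[0])],
                       [f"{species}c{i}" for i in range(arr.shape[1])],
                       species=species)


def test_restrict_matches_pairs_in_order(rng):
    cma = _cm(rng.integers(0, 5, (6, 4)), "lv")
    cmb = _cm(rng.integers(0, 5, (6, 3)), "he", species="B")
    om = OrthologMap([("lv3", "he1"), ("lv0", "he5")])
    ra, rb = restrict_to_orthologs(cma, cmb, om)
    assert ra.gene_ids == ["lv3", "lv0"]
    assert rb.gene_ids == ["he1", "he5"]
    assert np.array_equal(ra.counts.toarray(), cma.counts.toarray()[[3, 0]])


def test_restrict_drops_missing_pairs_with_warning(rng):
    cma = _cm(rng.integers(0, 5, (3, 4)), "lv")
    cmb = _cm(rng.integers(0, 5, (3, 4)), "he", species="B")
    om = OrthologMap([("lv0", "he0"), ("lvX", "he1")])
    with pytest.warns(UserWarning, match="dropped"):
        ra, rb = restrict_to_orthologs(cma, cmb, om)
    assert ra.gene_ids == ["lv0"]


def test_restrict_identity_is_identity(rng):
    cma = _cm(rng.integers(0, 5, (4, 5)))
    om = OrthologMap([(f"g{i}", f"g{i}") for i in range(4)])
    ra, rb = restrict_to_orthologs(cma, cma, om)
    assert np.array_equal(ra.counts.toarray(), cma.counts.toarray())


def test_restrict_empty_intersection_rejected(rng):
    cma = _cm(rng.integers(0, 5, (3, 4)), "lv")
    cmb = _cm(rng.integers(0, 5, (3, 4)), "he", species="B")
    with pytest.raises(ValueError, match="no ortholog"):
        restrict_to_orthologs(cma, cmb, OrthologMap([("x", "y")]))


def test_joint_embedding_identical_data_identical_coords(rng):
    x = rng.normal(size=(40, 25))
    ea, eb = joint_embedding_cca(x, x.copy(), k=5)
    assert np.abs(ea.coords - eb.coords).max() <= 1e-8


def test_joint_embedding_gene_permutation_invariance(rng):
    xa = rng.normal(size=(30, 20))
    xb = rng.normal(size=(30, 15))
    perm = rng.permutation(30)
    ea1, eb1 = joint_embedding_cca(xa, xb, k=4)
    ea2, eb2 = joint_embedding_cca(xa[perm], xb[perm], k=4)
    assert np.abs(ea1.coords - ea2.coords).max() <= 1e-8
    assert np.abs(eb1.coords - eb2.coords).max() <= 1e-8


def test_joint_embedding_singular_values_match_svd_oracle(rng):
    xa = rng.normal(size=(40, 60))
    xb = rng.normal(size=(40, 30))
    ea, eb = joint_embedding_cca(xa, xb, k=6)

    def std(x):
        mu = x.mean(1, keepdims=True)
        sd = x.std(1, keepdims=True)
        return (x - mu) / sd

    K = std(xa).T @ std(xb) / (40 - 1)
    s = np.linalg.svd(K, compute_uv=False)
    assert np.abs(ea.explained_variance - s[:6]).max() <= 1e-8


def test_joint_embedding_k_too_large(rng):
    with pytest.raises(ValueError):
        joint_embedding_cca(rng.normal(size=(5, 4)), rng.normal(size=(5, 4)), k=9)


def test_emd_identical_clouds_zero(rng):
    pts = rng.normal(size=(8, 3))
    w = rng.random(8)
    assert emd(pts, w, pts, w) <= 1e-10


def test_emd_two_atoms_closed_form():
    assert emd(np.array([[0.0]]), [1.0], np.array([[3.0]]), [1.0]) == \
        pytest.approx(3.0, abs=1e-10)


def test_emd_matches_dual_lp_oracle(rng):
    for _ in range(5):
        px = rng.normal(size=(6, 2))
        py = rng.normal(size=(6, 2))
        wx = rng.random(6)
        wy = rng.random(6)
        mine = emd(px, wx, py, wy)
        oracle = emd_dual_lp(px, wx, py, wy)
        assert mine == pytest.approx(oracle, abs=1e-8)


def test_emd_matches_hungarian_on_uniform_clouds(rng):
    px = rng.normal(size=(7, 3))
    py = rng.normal(size=(7, 3))
    mine = emd(px, np.ones(7), py, np.ones(7))
    assert mine == pytest.approx(emd_assignment_oracle(px, py), abs=1e-8)


def test_emd_metric_axioms(rng):
    """Identity, symmetry and triangle inequality on random 5-point clouds."""
    clouds = [(rng.normal(size=(5, 2)), rng.random(5) + 0.1)
              for _ in range(20)]
    for pts, w in clouds[:5]:
        assert emd(pts, w, pts, w) <= 1e-8
    for (px, wx), (py, wy) in zip(clouds[:10], clouds[10:]):
        d_xy = emd(px, wx, py, wy)
        d_yx = emd(py, wy, px, wx)
        assert d_xy == pytest.approx(d_yx, abs=1e-8)
    for i in range(0, 18, 3):
        (pa, wa), (pb, wb), (pc, wc) = clouds[i:i + 3]
        ab = emd(pa, wa, pb, wb)
        bc = emd(pb, wb, pc, wc)
        ac = emd(pa, wa, pc, wc)
        assert ac <= ab + bc + 1e-8


def test_emd_downsampling_is_deterministic(rng):
    pts = rng.normal(size=(500, 3))
    w = rng.random(500)
    py = rng.normal(size=(50, 3))
    wy = np.ones(50)
    v1 = emd(pts, w, py, wy, max_points=100, seed=7)
    v2 = emd(pts, w, py, wy, max_points=100, seed=7)
    assert v1 == v2


def test_emd_rejects_empty_cloud():
    with pytest.raises(ValueError):
        emd(np.empty((0, 2)), [], np.zeros((1, 2)), [1.0])


def _self_alignment_inputs(rng, n_t=4, n_per=15):
    coords = rng.normal(size=(n_t * n_per, 3))
    times = np.repeat(np.arange(n_t, dtype=float), n_per)
    probs = rng.dirichlet(np.ones(2), size=n_t * n_per)
    fm = FateMatrix(probs=probs, fate_names=["f1", "f2"],
                    reference_timepoint=float(n_t - 1))
    return coords, times, fm


def test_alignment_of_dataset_with_itself_is_identity(rng):
    coords, times, fm = _self_alignment_inputs(rng)
    res = align_timecourses(coords, times, coords, times, fm, fm,
                            {"f1": ("f1", "f1")}, seed=0)[0]
    assert res.best_pairs == [(t, t) for t in sorted(set(times))]
    assert np.allclose(np.diag(res.emd), 0.0, atol=1e-8)
    assert res.n_above_diagonal() == 0


def test_alignment_recovers_relabelled_shift(rng):
    """B identical to A with timepoints relabelled one step later."""
    coords, times, fm = _self_alignment_inputs(rng)
    res = align_timecourses(coords, times, coords, times + 1.0, fm, fm,
                            {"f1": ("f1", "f1")}, seed=0)[0]
    assert res.best_pairs == [(t, t + 1.0) for t in sorted(set(times))]
    assert res.n_above_diagonal() == len(res.best_pairs)


def test_alignment_flags_zero_weight_timepoints(rng):
    coords, times, fm = _self_alignment_inputs(rng)
    probs = fm.probs.copy()
    probs[times == 0.0, 0] = 0.0  # lineage f1 absent at the first timepoint
    fm2 = FateMatrix(probs=probs, fate_names=fm.fate_names,
                     reference_timepoint=fm.reference_timepoint)
    res = align_timecourses(coords, times, coords, times, fm2, fm2,
                            {"f1": ("f1", "f1")}, seed=0)[0]
    assert res.missing_rows == [0.0] and res.missing_cols == [0.0]
    assert all(t != 0.0 for t, _ in res.best_pairs)


def test_simulated_delay_recovered(alignment_run):
    """+3 h onset delay in species B shows up as a +3 h median best-pair
    offset (within one 3 h timepoint spacing) for at least 3 of 4 lineages."""
    from evodevo_ot.preprocess import normalize_log_cpm

    ra, rb = restrict_to_orthologs(alignment_run["sa_A"].merged,
                                   alignment_run["sa_B"].merged,
                                   alignment_run["om"])
    ea, eb = joint_embedding_cca(normalize_log_cpm(ra),
                                 normalize_log_cpm(rb), k=20)
    fa = alignment_run["fates_A"]
    fb = alignment_run["fates_B"]
    shared = [f for f in fa.fate_names if f in fb.fate_names]
    results = align_timecourses(ea.coords, alignment_run["times_A"],
                                eb.coords, alignment_run["times_B"],
                                fa, fb, {f: (f, f) for f in shared},
                                max_points=150, seed=1)
    hits = sum(abs(r.median_offset() - 3.0) <= 3.0 for r in results)
    assert len(results) == 4
    assert hits >= 3
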