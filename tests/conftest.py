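import numpy as np
import pytest

from evodevo_ot.io_formats import PipelineConfig
from evodevo_ot.pipeline import (all_timepoint_fates, preprocess_species,
                                 transport_species)
from evodevo_ot.synthetic_data import (alignment_scenario,
                                       interaction_scenario,
                                       simulate_two_species, tree_scenario)


@pytest.fixture(scope="session")
def tree_run():
    """Simulated 3-lineage data with preprocessing and transport for A."""
    cfg = tree_scenario(seed=1)
    mats_a, mats_b, cell_table, om, truth = simulate_two_species(cfg)
    pc = PipelineConfig(seed=1)
    sa = preprocess_species(mats_a, pc)
    totals = {t: float(cfg.expected_cells_per_timepoint[("A", t)])
              for t in sa.embedding_by_t}
    transport_species(sa, totals, pc)
    return dict(cfg=cfg, mats_a=mats_a, mats_b=mats_b, om=om, truth=truth,
                sa=sa, pc=pc)


@pytest.fixture(scope="session")
def alignment_run():
    """Two species with a +3 h global delay, fully processed for alignment."""
    cfg = alignment_scenario(seed=1)
    mats_a, mats_b, cell_table, om, truth = simulate_two_species(cfg)
    pc = PipelineConfig(seed=1, emd_max_points=150)
    out = dict(cfg=cfg, om=om, truth=truth, pc=pc)
    for species, mats in (("A", mats_a), ("B", mats_b)):
        sa = preprocess_species(mats, pc)
        totals = {t: float(cfg.expected_cells_per_timepoint[(species, t)])
                  for t in sa.embedding_by_t}
        transport_species(sa, totals, pc)
        fates, times = all_timepoint_fates(sa, truth.cells)
        out[f"sa_{species}"] = sa
        out[f"fates_{species}"] = fates
        out[f"times_{species}"] = times
    return out


@pytest.fixture(scope="session")
def interaction_run():
    """Conserved / lost / shifted(+6 h) interactions at 500 cells/timepoint."""
    cfg = interaction_scenario(seed=1)
    mats_a, mats_b, cell_table, om, truth = simulate_two_species(cfg)
    return dict(cfg=cfg, mats_a=mats_a, mats_b=mats_b, om=om, truth=truth)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
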