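import numpy as np
import pandas as pd
import pytest

from microrepeat.counts import CountTable, StudyDesign
from microrepeat.diversity import Phylogeny
from microrepeat.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def four_leaf_tree():
    """((A:1,B:1):1,(C:1,D:1):1); the hand-computation tree."""
    return Phylogeny.from_newick(["((A:1,B:1):1,(C:1,D:1):1);"])


@pytest.fixture
def toy_table():
    counts = np.array([
        [5, 0, 2],
        [0, 3, 2],
        [1, 1, 6],
    ])
    taxonomy = {
        "t1": "k__Bacteria;p__Proteobacteria;c__Gamma",
        "t2": "k__Bacteria;p__Proteobacteria;c__Alpha",
        "t3": "k__Bacteria;p__Firmicutes;c__Bacilli",
    }
    return CountTable(["t1", "t2", "t3"], ["L1", "L2", "L3"], counts, taxonomy)


@pytest.fixture
def toy_design():
    rows = []
    for f in range(1, 3):
        for j in range(1, 4):
            rows.append((f"L{f}.{j}", f"fish{f}", "fam1", "pop1",
                         ["PCP", "PFP", "DEP"][j - 1], "reproducibility"))
    return StudyDesign(pd.DataFrame(rows, columns=StudyDesign.REQUIRED))


@pytest.fixture(scope="session")
def small_sim():
    """A small but structured simulated dataset reused across tests."""
    cfg = SimulationConfig(n_populations=2, families_per_population=2,
                           fish_per_family=3, replicates_per_fish=3,
                           n_taxa=40, library_depth=3000,
                           sigma2_A=0.5, sigma2_W=0.05, seed=11)
    return simulate_dataset(cfg)
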