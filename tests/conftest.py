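import numpy as np
import pandas as pd
import pytest

import mockbias as mb
from mockbias.taxa import TaxonMeta

DESIGN_SEED = 1
TRUTH_SEED = 2


@pytest.fixture(scope="session")
def panel():
    return mb.vaginal_panel()


@pytest.fixture(scope="session")
def panel_names(panel):
    return [t.name for t in panel]


@pytest.fixture(scope="session")
def uniform_taxa():
    """Four taxa with identical copy number and genome size (no adjustment bias)."""
    return [TaxonMeta(f"t{i}", 1, 1.0, "+") for i in range(4)]


@pytest.fixture(scope="session")
def design80(panel_names):
    """The seven-taxon study layout: 63 support + 2 lack-of-fit + 15 replicates."""
    return mb.build_design(7, seed=DESIGN_SEED, taxa=panel_names)


@pytest.fixture(scope="session")
def default_truth():
    return mb.make_truth(7, "default", seed=TRUTH_SEED)


@pytest.fixture(scope="session")
def three_experiments(design80, default_truth, panel):
    """Simulated count tables for the cells / dna / pcr experiments."""
    return {
        exp: mb.simulate_experiment(design80, default_truth, panel, exp)
        for exp in ("cells", "dna", "pcr")
    }


@pytest.fixture(scope="session")
def three_proportions(three_experiments, panel):
    return {
        exp: mb.adjust_counts(three_experiments[exp], panel, exp)
        for exp in ("cells", "dna", "pcr")
    }


@pytest.fixture(scope="session")
def small_design():
    """A compact 4-component design with replicates, for cheap unit tests."""
    return mb.build_design(4, n_lack_of_fit=1, n_replicates=6, seed=7)
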