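import numpy as np
import pandas as pd
import pytest

from microgrowth.compositions import TaxonTable
from microgrowth.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def null_cohort():
    """A 200-subject cohort with no planted genus effects."""
    return simulate_cohort(SimulationConfig(n_subjects=200, seed=11))


@pytest.fixture(scope="session")
def planted_cohort():
    """A 300-subject cohort with a -0.3 Subdoligranulum effect at every lag."""
    return simulate_cohort(
        SimulationConfig(
            n_subjects=300, seed=23, effect_vector={"Subdoligranulum": -0.3}
        )
    )


@pytest.fixture
def toy_table():
    counts = pd.DataFrame(
        [[10, 30, 60, 0], [25, 25, 25, 25], [0, 5, 0, 1]],
        index=["s1", "s2", "s3"],
        columns=["Bacteroides", "Blautia", "Bifidobacterium", "Streptococcus"],
    )
    taxonomy = {
        "Bacteroides": "Bacteroidetes",
        "Blautia": "Firmicutes",
        "Bifidobacterium": "Actinobacteria",
        "Streptococcus": "Firmicutes",
    }
    return TaxonTable(counts, taxonomy)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
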