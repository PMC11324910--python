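import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from metaferm import simulate

logging.getLogger("metaferm").setLevel(logging.ERROR)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def small_tree():
    """4 genera x 2 species, 6-level taxonomy."""
    return simulate.simulate_taxonomy(4, 2)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact full synthetic dataset shared across read-only tests."""
    design = simulate.SimulationDesign(
        n_genera=4,
        genes_per_genus=15,
        conditions=("BLANK", "IMMP27", "IMMP94"),
        time_points_h=(0, 24, 48),
        seed=11,
    )
    return simulate.simulate_dataset(design)


@pytest.fixture(scope="session")
def enzyme_dictionary():
    df = pd.read_csv(DATA_DIR / "enzyme_names_synthetic.tsv", sep="\t")
    return dict(zip(df["name"], df["ec"]))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
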