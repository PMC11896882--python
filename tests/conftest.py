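import numpy as np
import pandas as pd
import pytest

from lianascape.config import SimulationConfig
from lianascape.synth import simulate

#: scaled-down single-plot layout (36 quadrats) with every effect knob at
#: zero: homogeneous liana rates, no environmental niches, no trait-niche
#: coupling, neutral host choice
NULL_KWARGS = dict(
    n_plots=1,
    plot_side=300.0,
    cell_size=3.0,
    n_liana_taxa=8,
    n_tree_species=10,
    liana_dominance=1.0,
    beta_structure={},
    env_niche_sd=0.0,
    trait_niche_correlation=0.0,
)


def null_config(seed: int, **overrides) -> SimulationConfig:
    kwargs = {**NULL_KWARGS, **overrides}
    return SimulationConfig(seed=seed, **kwargs)


@pytest.fixture(scope="session")
def demo_dataset():
    """One fixed scaled-down null dataset shared by structural tests."""
    return simulate(null_config(42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_stems():
    return pd.DataFrame({
        "stem_id": ["s1", "s2", "s3"],
        "species": ["A", "B", "A"],
        "plot_id": ["P1"] * 3,
        "x": [5.0, 15.0, 25.0],
        "y": [5.0, 15.0, 25.0],
        "dbh_census1": [12.0, 20.5, np.nan],
        "dbh_census2": [12.4, 21.0, 10.2],
        "wood_density": [0.55, 0.72, 0.55],
    })
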