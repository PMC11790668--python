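import numpy as np
import pandas as pd
import pytest

from forestdyn.biomass import SpeciesPool
from forestdyn.pipeline import PipelineConfig, compute_results
from forestdyn.simulate import SimulationConfig, simulate_study


@pytest.fixture
def tiny_pool() -> SpeciesPool:
    """Six species, two genera in each of two families, complete traits."""
    traits = pd.DataFrame(
        {
            "genus": ["g1", "g1", "g2", "g2", "g3", "g3"],
            "family": ["f1", "f1", "f1", "f2", "f2", "f2"],
            "wd": [0.40, 0.60, 0.55, 0.70, 0.45, 0.50],
            "hmax": [10.0, 20.0, 15.0, 25.0, 12.0, 18.0],
            "life_form": ["evergreen broad-leaved"] * 3 + ["deciduous broad-leaved"] * 2 + ["coniferous"],
            "a": [2.0, np.nan, 2.5, np.nan, 1.8, np.nan],
            "b": [0.5, np.nan, 0.6, np.nan, 0.55, np.nan],
            "cf": [1.0, np.nan, 1.05, np.nan, 1.0, np.nan],
            "region": ["subtropical"] * 6,
        },
        index=pd.Index([f"s{i}" for i in range(1, 7)], name="species"),
    )
    return SpeciesPool(traits, pooled_height=(2.0, 0.55, 1.02))


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=5, n_species=30, plot_cols=5, plot_rows=6, initial_stems_mean=60,
        habitat_fractions=(0.4, 0.35, 0.25),
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def small_results(small_study):
    """Full pipeline results on the small synthetic study."""
    pc = PipelineConfig(null_iterations=99, seed=5, min_stratum_n=5)
    return compute_results(
        small_study.censuses, small_study.species_pool,
        small_study.landscape.corner_elevations,
        small_study.landscape.frame["habitat"], pc,
    )
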