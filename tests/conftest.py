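import pandas as pd
import pytest

from seascape.simulate import (
    SimulationConfig,
    simulate_bgc_universe,
    simulate_genome_collection,
    simulate_profiles,
    simulate_reference_db,
)


@pytest.fixture(scope="session")
def cfg():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def universe(cfg):
    return simulate_bgc_universe(cfg)


@pytest.fixture(scope="session")
def reference(cfg, universe):
    _, _, truth = universe
    return simulate_reference_db(truth, cfg)


@pytest.fixture(scope="session")
def genome_collection(cfg):
    return simulate_genome_collection(cfg)


@pytest.fixture(scope="session")
def profiles(cfg, universe):
    _, bgcs, truth = universe
    return simulate_profiles(cfg, bgcs, truth)
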