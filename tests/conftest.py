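import numpy as np
import pandas as pd
import pytest

from habniche import CountTable, SimulationConfig, simulate_metacommunity


@pytest.fixture
def toy_table() -> CountTable:
    """Two habitats x two samples each, six taxa, hand-written counts."""
    counts = pd.DataFrame(
        {
            "w1": [10, 5, 0, 2, 0, 1],
            "w2": [10, 0, 0, 2, 0, 3],
            "g1": [0, 1, 8, 2, 5, 0],
            "g2": [0, 1, 8, 2, 5, 0],
        },
        index=[f"t{i}" for i in range(1, 7)],
    )
    habitat_of = pd.Series(
        {"w1": "water", "w2": "water", "g1": "gut", "g2": "gut"}
    )
    return CountTable(counts, habitat_of)


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully featured simulated metacommunity (shared, read-only)."""
    cfg = SimulationConfig(
        n_habitats=4,
        samples_per_habitat=10,
        natives_per_habitat=60,
        regional_generalists=15,
        depth=3000,
        seed=42,
    )
    table, metadata, truth = simulate_metacommunity(cfg)
    return cfg, table, metadata, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
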