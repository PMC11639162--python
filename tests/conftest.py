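import numpy as np
import pytest

from survbal import (
    CountTable,
    SimulationConfig,
    SurvivalOutcome,
    close_composition,
    simulate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_counts():
    return CountTable(
        sample_ids=("a", "b", "c", "d", "e"),
        taxon_ids=("t1", "t2", "t3", "t4"),
        counts=np.array([
            [10, 5, 0, 85],
            [20, 10, 1, 69],
            [5, 25, 0, 70],
            [15, 15, 2, 68],
            [30, 5, 0, 65],
        ]),
    )


@pytest.fixture
def toy_outcome():
    return SurvivalOutcome(
        time=np.array([3.0, 1.5, 4.2, 2.0, 5.1]),
        event=np.array([1, 1, 0, 1, 0]),
    )


@pytest.fixture(scope="session")
def strong_signal_data():
    """One moderately sized dataset with a planted 2-vs-2 balance."""
    cfg = SimulationConfig(
        n_samples=300, n_taxa=8, planted_plus=(0, 1), planted_minus=(2, 3),
        gamma_true=1.5, censoring_rate=0.2, seed=20240901,
    )
    data = simulate_dataset(cfg)
    return cfg, data, close_composition(data.counts)


@pytest.fixture(scope="session")
def null_data():
    cfg = SimulationConfig(
        n_samples=150, n_taxa=8, gamma_true=0.0, censoring_rate=0.2, seed=777,
    )
    data = simulate_dataset(cfg)
    return cfg, data, close_composition(data.counts)
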