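import dataclasses

import numpy as np
import pytest

from coreact.core import EventMatrix
from coreact.simulate import SimulationConfig, simulate_experiment


def tiny_matrix(rng: np.random.Generator, n_cells=5, n_frames=40,
                rate=30.0, p=0.15) -> EventMatrix:
    """A small random sparse event matrix for oracle-equivalence checks."""
    hits = rng.random((n_cells, n_frames)) < p
    values = np.where(hits, rng.lognormal(0.0, 0.5, hits.shape), 0.0)
    ts = np.arange(n_frames) * (1000.0 / rate)
    return EventMatrix(values, rate, ts, np.arange(n_cells))


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down high-shock configuration shared across tests."""
    return dataclasses.replace(
        SimulationConfig.high_shock(),
        n_cells=100,
        ensemble_sizes={"neutral": 20, "aversive": 20, "overlap": 15,
                        "remaining": 45},
        n_shared_encoding=30,
        n_extra_encoding=5,
        n_recall_cells=80,
        neutral_encoding_s=120.0,
        aversive_encoding_s=60.0,
        offline_s=300.0,
        recall_s=60.0,
        chemotag_s=2700.0,
        burst_rate_per_min=4.0,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    """One fully simulated small animal (all sessions), with ground truth."""
    return simulate_experiment(small_config, seed=123)
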