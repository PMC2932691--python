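import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from proteocnv.integrate import build_matched
from proteocnv.simulate import SimConfig, simulate_dataset

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A fast two-chromosome configuration for unit tests."""
    return SimConfig(n_chromosomes=2, genes_per_chromosome=80, seed=11)


@pytest.fixture(scope="session")
def small_data(small_cfg):
    return simulate_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_matched(small_data) -> pd.DataFrame:
    return build_matched(small_data.proteins, small_data.tumor_probes,
                         small_data.control_probes)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
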