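import numpy as np
import pytest

from droughtthresh import SimulationConfig, simulate
from droughtthresh.coincidence import response_curve


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_lat=5, n_lon=10, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate(small_config)


@pytest.fixture(scope="session")
def linked_dataset():
    """Grid with tree cover controlling the true threshold."""
    return simulate(SimulationConfig(n_lat=20, n_lon=20, seed=11, covariate_link=0.6))


def coupled_cluster(seed: int, n_cells: int = 100, truth: float = 15.0, **kwargs):
    """Pooled (sm, veg) arrays for one homogeneous strongly coupled cluster."""
    cfg = SimulationConfig(
        n_lat=1, n_lon=n_cells, seed=seed, true_threshold_pct=truth, **kwargs
    )
    ds = simulate(cfg)
    return ds.sm_cube.values, ds.veg_cubes[0].values


def cluster_curve(seed: int, n_cells: int = 100, truth: float = 15.0, **kwargs):
    sm, veg = coupled_cluster(seed, n_cells=n_cells, truth=truth, **kwargs)
    return response_curve(sm.ravel(), veg.ravel())
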