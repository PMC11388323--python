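import numpy as np
import pytest

from segflow import (
    GroundTruth,
    SimulationConfig,
    regress_out_confound,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def desk_cfg() -> SimulationConfig:
    """Small-but-realistic simulation: 4+4 subjects, 12x12x6 grid, 100 scans."""
    return SimulationConfig(
        n_subjects_per_group=4, n_scans=100, grid_shape=(12, 12, 6), seed=11
    )


@pytest.fixture(scope="session")
def desk_dataset(desk_cfg):
    return simulate_dataset(cfg=desk_cfg)


@pytest.fixture(scope="session")
def desk_residuals(desk_dataset):
    return [regress_out_confound(v, desk_dataset.rms) for v in desk_dataset.volumes]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def simple_truth() -> GroundTruth:
    return GroundTruth(
        boundary_times=np.array([30.0, 80.0, 130.0, 170.0]),
        boundary_salience=np.array([1.0, 0.6, 0.9, 0.8]),
    )
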