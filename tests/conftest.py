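import numpy as np
import pytest

from smforce import (
    EmissionModel,
    SensorCalibration,
    SyntheticScenario,
    generate_force_dataset,
)


@pytest.fixture(scope="session")
def calib():
    return SensorCalibration()


@pytest.fixture(scope="session")
def no_cell_dataset():
    """Medium cell-free dataset: no force, all mobile."""
    return generate_force_dataset(
        SyntheticScenario(n_tracks=500, cell_present=False, seed=101)
    )


@pytest.fixture(scope="session")
def mixture_dataset():
    """Cell dataset with 10% of tracks under 9 pN, 30% immobilized."""
    return generate_force_dataset(
        SyntheticScenario(
            n_tracks=400,
            phi_force=0.1,
            force_pN=9.0,
            phi_immobile=0.3,
            cell_present=True,
            seed=202,
        )
    )


@pytest.fixture(scope="session")
def emission():
    return EmissionModel()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
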