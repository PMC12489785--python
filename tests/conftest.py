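import numpy as np
import pytest

from ieegconn import SimConfig, generate_electrodes, simulate_patient


@pytest.fixture(scope="session")
def ecog_config():
    """Small noiseless ECoG patient: 4x4 grid, 8 stimulation pairs."""
    return SimConfig(
        modality="ECoG", grid_rows=4, grid_cols=4, fs=512.0,
        noise_uv=0.0, seed=7,
    )


@pytest.fixture(scope="session")
def seeg_config():
    """Small sEEG patient: 4 shafts x 8 contacts at 3.5 mm pitch."""
    return SimConfig(
        modality="sEEG", n_shafts=4, contacts_per_shaft=8, fs=512.0,
        noise_uv=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def ecog_patient(ecog_config):
    """Fully simulated noiseless ECoG patient (all pipeline inputs)."""
    return simulate_patient(ecog_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
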