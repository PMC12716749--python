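import numpy as np
import pytest

from sibcm.data_io import ParcellatedTimeSeries
from sibcm.dmf import DMFParameters
from sibcm.fixtures import make_modular_pattern, make_synthetic_subject


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def noise_series():
    """White-noise series: 200 samples x 6 regions, TR 1 s."""
    values = np.random.default_rng(7).standard_normal((200, 6))
    return ParcellatedTimeSeries(values, tr_seconds=1.0,
                                 region_ids=[f"R{i}" for i in range(6)])


@pytest.fixture(scope="session")
def modular_pattern():
    return make_modular_pattern(m=20, n_modules=4, seed=1)


@pytest.fixture(scope="session")
def small_subject(modular_pattern):
    """Short model-generated BOLD subject (M=20, 150 samples), shared across tests."""
    bold, truth = make_synthetic_subject(
        modular_pattern, DMFParameters(), duration_seconds=150 * 0.72,
        tr_out_seconds=0.72, seed=0, dt_seconds=0.002,
    )
    return bold, truth
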