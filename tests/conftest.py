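import numpy as np
import pytest

from circavar.dam_io import PhotoRegime
from circavar.synthetic_data import GenotypeSimParams, simulate_activity


@pytest.fixture(scope="session")
def regime():
    return PhotoRegime(lights_on=8.0, lights_off=20.0, n_ld_days=4, n_dd_days=6)


@pytest.fixture(scope="session")
def ld_regime():
    return PhotoRegime(lights_on=8.0, lights_off=20.0, n_ld_days=5, n_dd_days=0,
                       ld_analysis_days=3, dd_analysis_days=0)


@pytest.fixture(scope="session")
def control_params():
    """Well-entrained homogeneous genotype."""
    return GenotypeSimParams(
        genotype="ctrl", n_flies=10, mu=(0.5, 12.0), phi=(2.0, 5.0),
        beta12=(-2.5, 1.0, 0.0), beta21=(-1.5, 0.0, 0.0), sigma_u=0.0)


@pytest.fixture(scope="session")
def small_sim(control_params, regime):
    return simulate_activity(control_params, regime, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
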