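import numpy as np
import pytest

from decbct.decomposition import build_lut
from decbct.materials import get_material, make_basis_pair
from decbct.pipeline import preset_config, run_pipeline
from decbct.spectrum import generate_spectrum


@pytest.fixture(scope="session")
def water():
    return get_material("water")


@pytest.fixture(scope="session")
def graphite():
    return get_material("graphite")


@pytest.fixture(scope="session")
def aluminum():
    return get_material("aluminum")


@pytest.fixture(scope="session")
def basis():
    return make_basis_pair()


@pytest.fixture(scope="session")
def spectra_hl():
    """The 120/70 kVp tube spectra with 2.5 mm Al inherent filtration."""
    return generate_spectrum(120.0, 2.5), generate_spectrum(70.0, 2.5)


@pytest.fixture(scope="session")
def lut(basis, spectra_hl):
    sH, sL = spectra_hl
    return build_lut(basis, sH, sL)


@pytest.fixture(scope="session")
def desk_result():
    """Noiseless central-slice dual-energy run of the four-insert phantom."""
    return run_pipeline(preset_config("desk"))


@pytest.fixture(scope="session")
def uniformity_result():
    """Noiseless dual-energy run of the 150 mm uniform water cylinder."""
    return run_pipeline(preset_config("desk", phantom="uniformity"))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20150805)
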