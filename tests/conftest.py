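import pytest

from pmaalink.chromatogram import RtLibrary
from pmaalink.linkage import ResponseFactorLibrary
from pmaalink.simulate import default_species_profiles


@pytest.fixture(scope="session")
def rt_lib():
    return RtLibrary.default()


@pytest.fixture(scope="session")
def rf_lib():
    return ResponseFactorLibrary.default()


@pytest.fixture(scope="session")
def species_profiles():
    return default_species_profiles()
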