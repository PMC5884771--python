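import pytest

from semiqaf.cohort import fixture_table2
from semiqaf.phantoms import PhantomSpec, control_band


@pytest.fixture(scope="session")
def cohort16():
    return fixture_table2()


@pytest.fixture(scope="session")
def band_sw():
    return control_band(PhantomSpec(modality="SW"), n=8, seed=42)


@pytest.fixture(scope="session")
def band_nir():
    return control_band(PhantomSpec(modality="NIR"), n=8, seed=43)
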