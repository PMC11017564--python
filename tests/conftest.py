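import pytest

from pgatype.align import ScoringScheme
from pgatype.genotype import load_rules
from pgatype.simulate import generate_reference_panel


@pytest.fixture(scope="session")
def rules():
    return load_rules()


@pytest.fixture(scope="session")
def panel():
    """Default synthetic reference panel (realistic gene lengths)."""
    return generate_reference_panel(1)


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()
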