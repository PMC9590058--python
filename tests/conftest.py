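import pytest
from hypothesis import settings

from pedidose import AdultReference, Basis, DoseSpec

settings.register_profile("default", derandomize=True, max_examples=100)
settings.load_profile("default")


@pytest.fixture
def adult_ivig():
    """Adult polyclonal (IVIG-like) regimen: 400 mg/kg at the 70 kg reference."""
    return AdultReference(dose=DoseSpec(400.0, Basis.PER_KG, "mg"), weight_kg=70.0)
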