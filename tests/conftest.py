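import pytest
from hypothesis import settings

from rpmecon import ClinicParameters

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def defaults() -> ClinicParameters:
    """The published reference parameter set (100-patient clinic)."""
    return ClinicParameters()
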