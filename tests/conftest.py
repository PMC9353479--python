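import pytest
from hypothesis import HealthCheck, settings

from chipsim import run_collagenase_extraction, run_cytokine_enrichment

settings.register_profile(
    "chipsim",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("chipsim")


@pytest.fixture(scope="session")
def collagenase_result():
    """Full extraction scenario at shipped defaults (protective flow on)."""
    return run_collagenase_extraction()


@pytest.fixture(scope="session")
def collagenase_result_no_flow():
    """Same extraction setup with a zero hydrostatic head (unprotected)."""
    return run_collagenase_extraction(flow_enabled=False)


@pytest.fixture(scope="session")
def cytokine_result():
    """24 h chip-vs-Transwell secretion comparison at shipped defaults."""
    return run_cytokine_enrichment()
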