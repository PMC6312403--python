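import hypothesis
import pytest

from tirfquant.optics import illumination_profile
from tirfquant.translocation import solve_resting_density

hypothesis.settings.register_profile(
    "deterministic", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def canonical_grid():
    """50 layers of 10 nm with decay 0.008/nm — the standard biosensor grid."""
    return illumination_profile(0.008, 10.0, 50)


@pytest.fixture(scope="session")
def resting(canonical_grid):
    return solve_resting_density(canonical_grid)
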