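import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def binary_example():
    """Four cases, three agreements: the canonical worked example."""
    from kappaml import PairedRatings

    return PairedRatings.from_sequences(
        ["+", "+", "-", "+"], ["+", "-", "-", "+"]
    )


@pytest.fixture
def low_agreement_example():
    """Pa = 1/2 with both raters' '+' rate exactly 1/2."""
    from kappaml import PairedRatings

    return PairedRatings.from_sequences(
        ["+", "-", "+", "-"], ["+", "-", "-", "+"]
    )
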