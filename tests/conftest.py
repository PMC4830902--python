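import hypothesis
import pytest

from phrdiffusion import AdoptionSeries

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=60, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture
def observed_series() -> AdoptionSeries:
    """The observed US PHR adoption series (both-yes fraction per survey year)."""
    return AdoptionSeries([2008, 2011, 2013], [0.0516, 0.0980, 0.1717])
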