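import hypothesis

import pytest

from mdfkit import make_fixture, FIXTURE_NAMES

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    suppress_health_check=[hypothesis.HealthCheck.too_slow],
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(params=FIXTURE_NAMES)
def fixture_model(request):
    """Each of the generated demo models in turn."""
    return make_fixture(request.param)
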