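import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def main_scenario():
    from margingate import builtin_scenarios

    return next(s for s in builtin_scenarios() if s.id == "main")


@pytest.fixture
def event_catalog():
    from margingate import builtin_events

    return {e.name: e for e in builtin_events()}
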