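import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def instrument():
    from semas.instrument import default_instrument

    return default_instrument()


@pytest.fixture(scope="session")
def small_cohort(instrument):
    """Default-scenario cohort at n=204, fixed seed."""
    from semas.simulate import CohortConfig, simulate_cohort

    return simulate_cohort(CohortConfig(n=204, seed=42), instrument)


@pytest.fixture(scope="session")
def scored_cohort(instrument, small_cohort):
    from semas.scoring import score_cohort

    return score_cohort(small_cohort.semas_records, instrument)


def complete_record(instrument, code_index: int = 0, vas: float = 5.0):
    """A fully answered record using each scale's code at position
    ``code_index`` (from the top when negative)."""
    from semas.scoring import ResponseRecord

    responses = {}
    for item in instrument.items.values():
        if item.is_vas:
            responses[item.item_id] = vas
        else:
            responses[item.item_id] = item.scale.codes[code_index]
    return ResponseRecord(respondent_id="r1", responses=responses)


@pytest.fixture
def all_top_record(instrument):
    return complete_record(instrument, code_index=-1)
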