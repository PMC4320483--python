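import pytest

from modeshift import (
    CohortConfig,
    feature_table,
    filter_indoor,
    segment_traces,
    simulate_cohort,
)

#: Six-person cohort covering all five modes on both sides of many
#: 4/2 splits; small enough for exhaustive-combination tests.
MINI_ASSIGNMENT = {
    "q1": ("walk", "bike", "train"),
    "q2": ("bus", "car"),
    "q3": ("walk", "bike", "train"),
    "q4": ("bus", "car"),
    "q5": ("walk", "bike", "train"),
    "q6": ("bus", "car"),
}


def cohort_features(cohort):
    filtered = [piece for tr in cohort for piece in filter_indoor(tr)]
    return feature_table(segment_traces(filtered))


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def default_features(default_cohort):
    return cohort_features(default_cohort)


@pytest.fixture(scope="session")
def mini_config():
    return CohortConfig(
        n_persons=6,
        person_mode_assignment=MINI_ASSIGNMENT,
        commutes_per_person=1,
        seed=11,
    )


@pytest.fixture(scope="session")
def mini_cohort(mini_config):
    return simulate_cohort(mini_config)


@pytest.fixture(scope="session")
def mini_features(mini_cohort):
    return cohort_features(mini_cohort)
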