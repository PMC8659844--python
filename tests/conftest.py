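import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from coachcohort import (
    BASELINE,
    FINAL,
    AssessmentRecord,
    CohortDataset,
    DailyRecord,
    default_question_specs,
    default_variable_specs,
)


@pytest.fixture(scope="session")
def question_specs():
    return default_question_specs()


@pytest.fixture(scope="session")
def variable_specs():
    return default_variable_specs()


def make_assessment(pid, timepoint, variable_specs, rng=None, **overrides):
    """An assessment record with plausible values for every variable."""
    rng = rng or np.random.default_rng(0)
    base = {
        "chair_stand": 12.0, "arm_curl": 16.0, "two_minute_step": 65.0,
        "chair_sit_reach": -4.0, "back_scratch": -10.0, "foot_up_and_go": 6.3,
        "moca": 25.0, "mcs_a": 3.0, "mai": 6.0, "mna_mini": 4.0,
    }
    values = {
        var: base[var] + float(rng.normal(0, 1)) for var in variable_specs
    }
    values.update(overrides)
    return AssessmentRecord(pid, timepoint, values)


@pytest.fixture
def tiny_cohort(question_specs, variable_specs):
    """5 participants, 5 days, a couple of answers each day."""
    rng = np.random.default_rng(7)
    assessments = []
    daily = []
    for pid in ("a", "b", "c", "d", "e"):
        assessments.append(make_assessment(pid, BASELINE, variable_specs, rng))
        assessments.append(make_assessment(pid, FINAL, variable_specs, rng))
        for day in range(5):
            daily.append(
                DailyRecord(
                    pid,
                    day,
                    {
                        ("phys_light", 0): 2,
                        ("phys_light", 1): 1,
                        ("outside_house", 0): 1,
                        ("nut_water", 0): 3,
                        ("nut_salt", 0): 1,
                    },
                )
            )
    return CohortDataset(question_specs, variable_specs, assessments, daily, n_days=5)
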