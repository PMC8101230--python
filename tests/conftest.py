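import numpy as np
import pytest
from hypothesis import settings

from delirimpute import (
    BaseCohortParams,
    Cohort,
    Participant,
    ParticipantDay,
    generate_base_cohort,
    generate_outcome,
)

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


def make_participant(pid, statuses, sofa=None, outcome=None):
    """Build a Participant from a list of True/False/None daily statuses."""
    sofa = sofa or [10] * len(statuses)
    days = [
        ParticipantDay(pid, i + 1, s, sofa=sf)
        for i, (s, sf) in enumerate(zip(statuses, sofa))
    ]
    return Participant(pid, days, outcome=outcome)


@pytest.fixture
def table1_participant():
    """The illustrative record: present, present, missing, present, absent."""
    return make_participant("p1", [True, True, None, True, False])


@pytest.fixture(scope="session")
def base_cohort():
    """Fully observed synthetic base sample shared across tests."""
    return generate_base_cohort(BaseCohortParams(n_base=1000), rng=1)


@pytest.fixture(scope="session")
def outcome_cohort(base_cohort):
    """Base cohort with generated outcomes (slope -1, residual SD 12)."""
    return generate_outcome(base_cohort, rng=7)


def cohort_from_statuses(status_lists, outcomes=None, sofa_lists=None):
    parts = []
    for i, statuses in enumerate(status_lists):
        sofa = sofa_lists[i] if sofa_lists else None
        outcome = outcomes[i] if outcomes is not None else None
        parts.append(make_participant(i, statuses, sofa=sofa, outcome=outcome))
    return Cohort.from_participants(parts)
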