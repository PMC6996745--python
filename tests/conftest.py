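import pytest

from emamotives import (
    CohortDataset,
    EatingEvent,
    MotiveCatalog,
    TraitProfile,
    studylike_config,
    run_analysis,
    simulate_cohort,
)

CAT = MotiveCatalog()


def ratings(value=2.0, **overrides):
    """A full 15-motive rating map at a constant value with overrides."""
    r = {m: float(value) for m in CAT}
    r.update({k: float(v) for k, v in overrides.items()})
    return r


@pytest.fixture
def tiny_cohort():
    """Two participants, four events — the smallest fixture exercising every path."""
    traits = [
        TraitProfile("A", ratings(2, liking=4, habit=3)),
        TraitProfile("B", ratings(1, liking=3, price=2)),
    ]
    events = [
        EatingEvent("A", 1, "breakfast", ratings(2, liking=2)),
        EatingEvent("A", 1, "lunch", ratings(2, liking=4)),
        EatingEvent("A", 2, "dinner", ratings(3, liking=3)),
        EatingEvent("B", 1, "snack", ratings(1, liking=2)),
    ]
    return CohortDataset(traits=traits, events=events).validate()


@pytest.fixture(scope="session")
def studylike_cohort():
    return simulate_cohort(studylike_config(seed=1))


@pytest.fixture(scope="session")
def studylike_runs():
    """Full pipeline on 20 studylike seeds — shared by recovery/power checks."""
    return [run_analysis(simulate_cohort(studylike_config(seed=s))) for s in range(1, 21)]
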