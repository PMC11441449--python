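import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_grid():
    from scotoperim import build_grid

    return build_grid()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Small simulated cohort with retest, shared across tests."""
    from scotoperim import SyntheticCohortConfig, simulate_cohort

    return simulate_cohort(SyntheticCohortConfig(n_per_group=4, seed=7))


def make_exam(grid, thresholds, *, color="cyan_505nm", eye="OD",
              trace=((0.0, 0.0),) * 5, catch=(False,) * 10,
              subject="S01", session="test1", condition="scotopic"):
    from scotoperim import Color, Condition, Exam, Eye, Session

    return Exam(
        subject_id=subject, eye=Eye(eye), condition=Condition(condition),
        color=Color(color), grid=grid, thresholds=tuple(thresholds),
        fixation_trace=tuple(trace), catch_trials=tuple(catch),
        duration_s=300.0, session=Session(session),
    )
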