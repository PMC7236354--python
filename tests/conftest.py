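import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from icatest import (
    Session,
    TrialRecord,
    build_trial_schedule,
    generate_mask_pool,
    generate_stimulus_set,
)


@pytest.fixture(scope="session")
def mask_pool():
    return generate_mask_pool(64, seed=7)


@pytest.fixture(scope="session")
def stimset():
    return generate_stimulus_set(seed=1)


@pytest.fixture(scope="session")
def schedule(stimset, mask_pool):
    return build_trial_schedule(stimset, mask_pool, order_seed=5)


def make_trial(i, correct=True, rt=500.0, phase="main", label="animal",
               responded=True):
    """Consistent TrialRecord; set responded=False for a non-response."""
    if not responded:
        response, correct, rt = "none", False, None
    else:
        response = label if correct else ("non_animal" if label == "animal" else "animal")
    return TrialRecord(trial_index=i, image_id=f"img{i:03d}", true_label=label,
                       phase=phase, response=response, correct=correct, rt_ms=rt)


def make_session(rts, correct=None, practice_correct=10, subject_id="s1"):
    """Session with a 10-trial practice block and one main trial per RT.

    rts: iterable of reaction times (None = non-response);
    correct: parallel booleans (default all True).
    """
    records = [
        make_trial(i, correct=i < practice_correct, phase="practice_1")
        for i in range(10)
    ]
    if correct is None:
        correct = [True] * len(rts)
    for j, (rt, ok) in enumerate(zip(rts, correct)):
        records.append(
            make_trial(10 + j, correct=ok, rt=rt, responded=rt is not None)
        )
    return Session(subject_id=subject_id, practice_outcome="passed_first",
                   records=records)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
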