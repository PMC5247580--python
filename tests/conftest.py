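import numpy as np
import pandas as pd
import pytest

import cardiogate as cg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def wit_design():
    return cg.DesignSpec.wit()


@pytest.fixture
def small_wit():
    """WIT design shrunk to 6 trials per cell for fast cohort tests."""
    return cg.DesignSpec.wit(trials_per_cell=6)


@pytest.fixture
def fast_behavior():
    """Behavior model with no misses and latencies far below the deadline,
    so accuracy reflects p_correct alone."""
    return cg.BehaviorModelParams(
        p_correct=cg.default_p_correct("wit"),
        miss_rate=0.0,
        rt_mean=300.0,
        rt_sd=15.0,
        seed=5,
    )


@pytest.fixture
def small_cohort(small_wit, fast_behavior):
    heart = cg.HeartModelParams(seed=3)
    return cg.generate_cohort(small_wit, heart, fast_behavior, n_subjects=4)


def make_trials(records):
    """Build a minimal analysed-trial table from per-trial tuples
    (subject, prime, object, phase, on_time, correct)."""
    return pd.DataFrame(
        records,
        columns=["subject_id", "prime", "object", "recoded_phase", "on_time",
                 "correct"],
    )
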