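import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


def make_trials(rows):
    """Build a trial table from (subject, idx, emotion, gender, response, rt)."""
    return pd.DataFrame(rows, columns=[
        "subject_id", "trial_index", "emotion", "stimulus_gender", "response", "rt_s"])


@pytest.fixture
def simple_trials():
    """Three subjects with clean, obviously-typed trials."""
    rows = []
    for sid in ("s1", "s2", "s3"):
        for i in range(1, 11):
            rows.append((sid, i, "neutral", "male" if i % 2 else "female",
                         "male" if i % 2 else "female", 0.5 + 0.01 * i))
    return make_trials(rows)
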