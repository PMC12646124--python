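import numpy as np
import pandas as pd
import pytest

from cmtiming.forest import ForestConfig
from cmtiming.scoring import long_to_wide
from cmtiming.subscales import AGES_FULL, SUBSCALES
from cmtiming.synthetic import SyntheticSpec, generate_cohort


def make_wide(scores: dict[tuple[str, int], float], subjects=("s1",)) -> pd.DataFrame:
    """Wide chronology frame from a sparse {(subscale, age): score} dict."""
    rows = []
    for sid in subjects:
        for (sub, age), score in scores.items():
            rows.append({"subject_id": sid, "subscale": sub, "age": age, "score": score})
    if not rows:  # all-zero chronology
        rows = [
            {"subject_id": sid, "subscale": SUBSCALES[0], "age": 1, "score": 0.0}
            for sid in subjects
        ]
    return long_to_wide(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_cohort():
    """Default-structure cohort with planted effects, small enough for unit tests."""
    return generate_cohort(SyntheticSpec(n_subjects=150, seed=11))


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort whose outcomes are independent of every predictor."""
    return generate_cohort(SyntheticSpec(n_subjects=200, effect_map=[], seed=13))


@pytest.fixture
def fast_forest():
    """Small ensemble for unit tests where only the mechanics matter."""
    return ForestConfig(n_trees=15, max_depth=5, n_split_reps=5, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def flat_prevalence(value: float = 0.0, overrides: dict[str, float] | None = None):
    prev = pd.DataFrame(value, index=list(SUBSCALES), columns=list(AGES_FULL), dtype=float)
    for sub, p in (overrides or {}).items():
        prev.loc[sub] = p
    return prev
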