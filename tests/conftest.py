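import numpy as np
import pytest

from rdscreen.data_model import N_ITEMS, RespondentRecord, item_ids
from rdscreen.synthetic_cohort import (
    EffectSpec,
    generate_cohort,
    shift_profile,
    uniform_profile,
)


def make_record(record_id="r1", answer=1, age=40, gender="F", diagnosis="PAH", group="RD", **kwargs):
    """A complete record with a constant answer, overridable field-wise."""
    answers = kwargs.pop("answers", [answer] * N_ITEMS)
    return RespondentRecord(
        record_id=record_id,
        answers=answers,
        age=age,
        gender=gender,
        diagnosis=diagnosis,
        group=group,
        **kwargs,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def small_cohort():
    """A well-separated 30 RD vs 30 NRO cohort for fast pipeline tests."""
    base = uniform_profile("base")
    profiles = {
        "PAH": shift_profile(base, EffectSpec(delta=0.8), label="RD"),
        "NRO": uniform_profile("NRO"),
    }
    return generate_cohort(profiles, 30, seed=7)


@pytest.fixture(scope="session")
def toy_xy():
    """Linearly separable 2-feature toy problem, 10 points per class."""
    rng = np.random.default_rng(3)
    X0 = rng.normal([-3.0, -3.0], 0.3, size=(10, 2))
    X1 = rng.normal([3.0, 3.0], 0.3, size=(10, 2))
    X = np.vstack([X0, X1])
    y = np.array([0] * 10 + [1] * 10)
    return X, y


def brute_force_auc(pairs):
    """Independent AUC oracle: exhaustive pair counting, ties worth half.

    ``pairs`` is a list of (label, score) with label 0 the positive
    (rare-disease) side and the score the probability of that side.
    """
    pos = [s for lab, s in pairs if lab == 0]
    neg = [s for lab, s in pairs if lab == 1]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
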