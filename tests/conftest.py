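import numpy as np
import pandas as pd
import pytest

from dccn.data_io import COHORT_COLUMNS, IntakeMatrix


def make_cohort(n: int, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Minimal valid cohort frame with n healthy retained-by-default rows."""
    rng = rng or np.random.default_rng(0)
    idx = pd.Index([f"P{i:04d}" for i in range(n)], name="participant_id")
    df = pd.DataFrame(
        {
            "sex": rng.choice(["male", "female"], size=n),
            "age": rng.uniform(40, 75, size=n),
            "education_high": rng.random(n) < 0.3,
            "exercise_regular": rng.random(n) < 0.2,
            "smoking": rng.choice(["never", "former", "current"], size=n),
            "alcohol": rng.exponential(10, size=n),
            "bmi": rng.normal(24, 3, size=n),
            "fbg_baseline": rng.uniform(70, 110, size=n),
            "on_antidiabetic_meds": np.zeros(n, dtype=bool),
            "person_years": rng.uniform(1, 10, size=n),
            "incident_t2d": np.zeros(n, dtype=bool),
            "diagnosis_visit": np.full(n, np.nan),
        },
        index=idx,
    )
    return df[list(COHORT_COLUMNS)]


def make_intake(cohort: pd.DataFrame, foods=("rice", "veg", "fish"),
                rng: np.random.Generator | None = None) -> IntakeMatrix:
    rng = rng or np.random.default_rng(1)
    frame = pd.DataFrame(
        rng.gamma(2.0, 0.5, size=(len(cohort), len(foods))),
        index=cohort.index, columns=list(foods),
    )
    energy = pd.Series(rng.normal(1600, 300, size=len(cohort)),
                       index=cohort.index, name="energy_kcal")
    return IntakeMatrix(frames={1: frame}, energy={1: energy})


@pytest.fixture
def small_cohort():
    cohort = make_cohort(50)
    return cohort, make_intake(cohort)
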