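import numpy as np
import pandas as pd
import pytest

from shiftuse import BEHAVIORS, default_plan
from shiftuse import synth


@pytest.fixture(scope="session")
def plan():
    return default_plan()


@pytest.fixture(scope="session")
def small_cohort(plan):
    """Full epoch-level cohort: 12 participants, 7 anchored days."""
    return synth.generate_cohort(plan, seed=11, n_participants=12, n_days=7)


@pytest.fixture(scope="session")
def records66(plan):
    """Participant table at the study's sample size."""
    return synth.generate_participant_table(plan, 66, seed=42)


@pytest.fixture(scope="session")
def records500(plan):
    return synth.generate_participant_table(plan, 500, seed=42)


def make_regression_dataset(rng: np.random.Generator, n: int = 100) -> pd.DataFrame:
    """Random full-rank participant table for algebraic-oracle tests."""
    df = pd.DataFrame({"participant_id": [f"R{i:04d}" for i in range(n)]})
    df["age"] = rng.normal(40, 10, n)
    df["alcohol"] = rng.integers(0, 2, n)
    for day_type in ("workday", "leisure"):
        for b in BEHAVIORS:
            df[f"{day_type}_{b.lower()}"] = rng.uniform(30, 600, n)
    df["wc"] = rng.normal(85, 9, n)
    df["weight"] = rng.normal(70, 10, n)
    df["tg"] = 10 ** rng.normal(2.0, 0.3, n)
    return df
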