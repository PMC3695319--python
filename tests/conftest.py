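import numpy as np
import pandas as pd
import pytest

from vbmtraj.simulate import generate_cohort


def make_cohort(ages_asd, ages_ctrl, seed=0):
    """Hand-built cohort with prescribed ages and seeded covariates."""
    rng = np.random.default_rng(seed)
    rows = []
    for g, ages in (("ASD", ages_asd), ("CTRL", ages_ctrl)):
        for i, age in enumerate(ages):
            rows.append(
                {
                    "subject_id": f"{g}{i:03d}",
                    "group": g,
                    "age": float(age),
                    "fsiq": float(rng.normal(110, 14)),
                    "viq": float(rng.normal(108, 17)),
                    "piq": float(rng.normal(105, 14)),
                    "tbv": float(rng.normal(1374, 126)),
                    "scanner": "A",
                    "ados": float(rng.normal(12, 3)) if g == "ASD" else np.nan,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def cohort5():
    """Five subjects, two groups — the smallest fixture with a full design."""
    return make_cohort([10.0, 20.0, 30.0], [15.0, 25.0], seed=11)


@pytest.fixture
def cohort12():
    """Twelve subjects across a broad age span."""
    return make_cohort(
        [9, 13, 17, 21, 26, 33], [10, 14, 19, 24, 30, 41], seed=7
    )


@pytest.fixture
def cohort80():
    """A study-sized generated cohort (40 per group)."""
    return generate_cohort(40, 40, seed=42)
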