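import numpy as np
import pandas as pd
import pytest

from miprofile import (
    BehavioralTable,
    CLASSIFICATION_VARS,
    generate_profile_cohort,
    train_classifier,
)
from miprofile.cohort import default_cohort_config

#: Separation scale in the neighborhood the 94%-LOO calibration selects;
#: fixtures use it directly so unit tests avoid re-running the calibration.
FIXTURE_SCALE = 1.45


def make_small_table(n=6, missing=(), with_label=False, seed=0):
    """Tiny hand-sized behavioral table for I/O and edge-case tests."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "id": [f"p{i:03d}" for i in range(n)],
            "sex": rng.choice(["F", "M"], size=n),
            "site": rng.choice([f"site{i}" for i in range(1, 9)], size=n),
            "age": rng.uniform(6.5, 12.5, size=n).round(3),
            **{
                v: rng.normal(100, 15, size=n).round(2)
                for v in CLASSIFICATION_VARS
            },
        }
    )
    if with_label:
        df["label"] = rng.choice(
            ["PoorDecoder", "PoorComprehender", "GenerallyPoorReader", "Control"], size=n
        )
    for row, col in missing:
        df.loc[row, col] = np.nan
    return BehavioralTable(df)


@pytest.fixture(scope="session")
def training_cohort():
    """198-row labeled cohort at a separation close to the calibrated one."""
    return generate_profile_cohort(default_cohort_config(seed=11).with_separation(FIXTURE_SCALE))


@pytest.fixture(scope="session")
def trained_model(training_cohort):
    return train_classifier(training_cohort, seed=11, tune=False, mtry=2)
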