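import numpy as np
import pandas as pd
import pytest

from fabrykit.report import annotate_cohort
from fabrykit.simulate import GroupEffect, SimConfig, generate_cohort


@pytest.fixture(scope="session")
def dense_config():
    """Small cohort with inflated carrier frequencies so every unit test has
    carriers to work with (machinery tests, not calibration tests)."""
    return SimConfig(
        n_males=6000,
        n_females=6000,
        seed=123,
        carrier_freq_by_group={"ALL_C": 0.03, "ALL_P": 0.02, "ALL_U": 0.015},
        effect_model={
            "ALL_P": GroupEffect(beta_main=np.log(5.0), uacr_multiplier=4.0),
            "ALL_C": GroupEffect(beta_main=np.log(0.8), beta_interaction=np.log(2.5)),
            "ALL_U": GroupEffect(),
        },
    )


@pytest.fixture(scope="session")
def dense_cohort(dense_config):
    return generate_cohort(dense_config)


@pytest.fixture(scope="session")
def annotated(dense_cohort):
    return annotate_cohort(dense_cohort.table)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_2x2(a, b, c, d):
    """Rows for a 2x2 table: a exposed cases, b exposed controls, c / d unexposed."""
    return pd.DataFrame(
        {
            "carrier": [1] * (a + b) + [0] * (c + d),
            "y": [1] * a + [0] * b + [1] * c + [0] * d,
        }
    )
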