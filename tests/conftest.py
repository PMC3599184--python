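import numpy as np
import pandas as pd
import pytest

from raiaudit.cohort import CohortConfig, ErrorRates, generate_cohort, paper_shape_preset
from raiaudit.dictionary import default_dictionary
from raiaudit import pipeline


@pytest.fixture(scope="session")
def dictionary():
    return default_dictionary()


@pytest.fixture(scope="session")
def small_cohort(dictionary):
    """Small clean preset cohort shared by unit tests."""
    config = paper_shape_preset(seed=11, records_per_quarter=400, n_quarters=6)
    frame, truth = generate_cohort(config, dictionary)
    return config, frame, truth


@pytest.fixture(scope="session")
def acceptance_cohort(dictionary):
    """Clean study-scale cohort (2,000 records/quarter over 20 quarters)."""
    config = paper_shape_preset(seed=20, records_per_quarter=2000, n_quarters=20)
    frame, truth = generate_cohort(config, dictionary)
    return config, frame, truth


@pytest.fixture(scope="session")
def scored_small(small_cohort, dictionary):
    _, frame, _ = small_cohort
    return pipeline.prepare(frame, dictionary)


def base_record(**overrides):
    """A complete, internally consistent record mapping for rule tests.

    Every declared item defaults to 0 (a fully independent, error-free
    resident); overrides set the condition under test.
    """
    rec = {c: 0 for c in default_dictionary().codes}
    rec.update(
        height_cm=165,
        weight_kg=70,
        birthdate=pd.Timestamp("1930-06-15"),
        reference_date=pd.Timestamp("2008-03-10"),
        signoff_date=pd.Timestamp("2008-03-12"),
    )
    rec.update(overrides)
    return rec
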