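"""Shared study conditions for the numbered analysis scripts.

One synthetic two-sector cohort (600 records/quarter over 12 quarters,
seed 42) with a 2% injection rate for every error family; each script
regenerates it deterministically so the scripts can run in any order.
"""
from raiaudit.cohort import ErrorRates, generate_cohort, inject_errors, paper_shape_preset
from raiaudit.dictionary import default_dictionary

SEED = 42
RECORDS_PER_QUARTER = 600
N_QUARTERS = 12
ERROR_RATE = 0.02

DICTIONARY = default_dictionary()


def clean_cohort():
    config = paper_shape_preset(seed=SEED, records_per_quarter=RECORDS_PER_QUARTER,
                                n_quarters=N_QUARTERS)
    frame, truth = generate_cohort(config, DICTIONARY)
    return config, frame, truth


def injected_cohort():
    config = paper_shape_preset(seed=SEED, records_per_quarter=RECORDS_PER_QUARTER,
                                n_quarters=N_QUARTERS,
                                error_rates=ErrorRates.uniform(ERROR_RATE))
    frame, truth = clean_cohort()[1:]
    return config, *inject_errors(frame, config, truth, DICTIONARY)
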