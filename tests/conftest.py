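import numpy as np
import pytest
from dataclasses import replace

from meganorm import default_region_table, generate_cohort, run_pipeline
from meganorm.synthetic import null_spec


@pytest.fixture(scope="session")
def table():
    return default_region_table(seed=7)


@pytest.fixture(scope="session")
def small_null_cohort(table):
    """Exchangeable two-cohort study, reduced size and counts for speed."""
    spec = replace(null_spec(seed=42), n_subjects_norm=40, n_subjects_clin=20,
                   followup_fraction=0.5, total_count_mean=60_000.0)
    return spec, generate_cohort(spec, table)


@pytest.fixture(scope="session")
def small_pipeline(table, small_null_cohort):
    _, cohort = small_null_cohort
    return run_pipeline(cohort, table)
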