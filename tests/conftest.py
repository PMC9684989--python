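"""Shared fixtures: generated study cohorts and their classifications."""

import pytest

from fibralg import (
    ClassifierConfig,
    builtin_step1_spec,
    builtin_step2_spec,
    classify_cohort,
    generate,
    significance_table,
)


@pytest.fixture(scope="session")
def step1_records():
    """150-patient significance cohort, exact counts, fixed seed."""
    return generate(builtin_step1_spec(seed=7))


@pytest.fixture(scope="session")
def step2_records():
    """100-patient validation cohort, exact counts, fixed seed."""
    return generate(builtin_step2_spec(seed=7))


@pytest.fixture(scope="session")
def step2_traces(step2_records):
    return classify_cohort(step2_records, ClassifierConfig())


@pytest.fixture(scope="session")
def step1_significance(step1_records):
    return significance_table(step1_records, correction="none")
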