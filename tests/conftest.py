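import dataclasses

import pytest
from hypothesis import settings

from mhfii_foodsec.ffq import load_default_schema
from mhfii_foodsec.mhfii import load_default_scoring_table
from mhfii_foodsec.synthetic import GeneratorConfig, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scoring_table():
    return load_default_scoring_table()


@pytest.fixture(scope="session")
def schema():
    return load_default_schema()


@pytest.fixture(scope="session")
def default_cohort():
    """One study-sized cohort under the calibrated defaults."""
    return generate_cohort(GeneratorConfig(seed=0)).frame


@pytest.fixture(scope="session")
def small_cohort():
    cfg = dataclasses.replace(GeneratorConfig(), n=1500, seed=42)
    return generate_cohort(cfg).frame
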