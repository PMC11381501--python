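import pytest

from icfhear import canonical_bank, generate_cohort, generate_worked_fixture
from icfhear.synthetic import GeneratorConfig


@pytest.fixture(scope="session")
def bank():
    return canonical_bank()


@pytest.fixture(scope="session")
def default_cohort(bank):
    cohort, truth = generate_cohort(GeneratorConfig(seed=1), bank)
    return cohort, truth


@pytest.fixture(scope="session")
def worked(bank):
    return generate_worked_fixture(bank)
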