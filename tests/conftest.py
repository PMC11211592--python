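import pytest

from pvhepascan.dedup import deduplicate
from pvhepascan.fixture import EXPECTED, fixture_small
from pvhepascan.synthetic import default_config, generate


@pytest.fixture(scope="session")
def fixture_dataset():
    return fixture_small()


@pytest.fixture(scope="session")
def fixture_expected():
    return dict(EXPECTED)


@pytest.fixture(scope="session")
def fixture_store(fixture_dataset):
    """Deduplicated fixture ready for cohort/descriptive stages."""
    return deduplicate(fixture_dataset.pooled).store


@pytest.fixture(scope="session")
def synth_dataset():
    """A mid-size generated dataset shared across statistical tests."""
    return generate(default_config(n_cases=20_000, seed=11))


@pytest.fixture(scope="session")
def synth_store(synth_dataset):
    return deduplicate(synth_dataset.pooled).store
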