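import pytest

from burdenscope import (
    FilterConfig,
    SimulationConfig,
    filter_cohort,
    load_table1_fixture,
    make_truth,
)


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def table1_filtered(table1):
    return filter_cohort(table1, FilterConfig())


@pytest.fixture(scope="session")
def small_config():
    """Small synthetic study shared by read-only tests."""
    return SimulationConfig(
        n_genes=200, n_positive_training=30, n_negative_training=80, seed=11
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return make_truth(small_config)
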