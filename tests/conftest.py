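import pytest

from edcnet.synthetic import SyntheticConfig, fixture_path, generate


@pytest.fixture(scope="session")
def table1_path():
    return fixture_path("table1_chemical_gene.tsv")


@pytest.fixture(scope="session")
def table2_path():
    return fixture_path("table2_network_layers.tsv")


@pytest.fixture(scope="session")
def table3_path():
    return fixture_path("table3_candidates.tsv")


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(random_seed=1)


@pytest.fixture(scope="session")
def bundle_and_truth(tmp_path_factory, default_config):
    """One default synthetic bundle (seed=1) shared across the suite."""
    outdir = tmp_path_factory.mktemp("bundle")
    return generate(default_config, outdir)


@pytest.fixture(scope="session")
def bundle(bundle_and_truth):
    return bundle_and_truth[0]


@pytest.fixture(scope="session")
def truth(bundle_and_truth):
    return bundle_and_truth[1]
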