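import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "fixed", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")

from strandscape.synthetic import build_toy_genome


@pytest.fixture(scope="session")
def truth():
    return build_toy_genome()


@pytest.fixture(scope="session")
def index(truth):
    return truth.partition()


@pytest.fixture(scope="session")
def genes(truth):
    return truth.collapsed_genes()


@pytest.fixture(scope="session")
def genome_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("toy_genome")
    build_toy_genome(out)
    return out
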