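import pytest

from tsplice import Genome, SampleRoles
from tsplice.fixtures import default_fixture_config, generate_fixture


@pytest.fixture
def toy_genome() -> Genome:
    return Genome({"chr1": "AAAACCCCGGGG"})


@pytest.fixture
def roles() -> SampleRoles:
    return SampleRoles(
        target_stage_samples=("early", "late1", "late2", "late3"),
        off_target_samples=("gx_male", "ovary", "female"),
    )


@pytest.fixture(scope="session")
def fixture_run(tmp_path_factory):
    """The standard 30-gene validation fixture (seed 42), generated once."""
    out = tmp_path_factory.mktemp("fixture")
    truth = generate_fixture(default_fixture_config(42), out)
    return out, truth
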