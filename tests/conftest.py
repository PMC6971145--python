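import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from bfbl import SynthConfig, curate, generate, standard_fixture


@pytest.fixture(scope="session")
def std_fixture():
    return standard_fixture()


@pytest.fixture(scope="session")
def std_result(std_fixture):
    return curate(std_fixture.records, std_fixture.evidence, null_slots=std_fixture.null_slots)


@pytest.fixture(scope="session")
def synth_run():
    """Planted generator output (seed 1) and its curation result."""
    gen = generate(SynthConfig(seed=1))
    result = curate(gen.records, gen.evidence)
    return gen, result
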