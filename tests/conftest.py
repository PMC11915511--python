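import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def corpus(tmp_path):
    """A deterministic small corpus with planted truth."""
    from rnacurate.fixtures import generate_corpus, random_fixture_spec, run_config_for

    spec = random_fixture_spec(seed=7, max_entries=10)
    out = tmp_path / "corpus"
    truth = generate_corpus(spec, out)
    return spec, truth, run_config_for(spec, out), out
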