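import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def demo_bundle():
    """The packaged demonstration study (seed 42), generated once."""
    from xenoscan.simulate import demo_config, generate_study

    return generate_study(demo_config(seed=42))


@pytest.fixture(scope="session")
def demo_paths(demo_bundle, tmp_path_factory):
    """Demo study written to disk (transcripts/mirnas/annotation/truth)."""
    out = tmp_path_factory.mktemp("demo_study")
    return demo_bundle.write(out)
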