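import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "allseq",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("allseq")


@pytest.fixture(scope="session")
def small_genome():
    """A 200 kb two-chromosome random genome shared by read-level tests."""
    from allseq.simulate import SimulationConfig, make_genome

    cfg = SimulationConfig(genome_length=200_000, n_chromosomes=2, seed=7)
    return make_genome(cfg)
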