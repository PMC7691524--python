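import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_fixture():
    """A small simulated dataset shared across integration tests."""
    from transieve import simulate as sim

    cfg = sim.FixtureConfig(seed=11, n_genes=12, n_transcripts=60)
    genome, models = sim.make_genome(cfg)
    seqs, truth = sim.make_transcript_set(genome, models, cfg)
    records = sim.make_alignments(truth, models, cfg, genome)
    return cfg, genome, models, seqs, truth, records
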