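import pytest

from camseq.simulate import (
    SimulationConfig,
    assign_methylation,
    build_transcriptome,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_transcripts=10, n_reads=5000, seed=11)


@pytest.fixture(scope="session")
def small_library(small_config):
    """A 10-transcript synthetic library shared across read-level tests."""
    transcripts = build_transcriptome(small_config)
    truth = assign_methylation(transcripts, small_config)
    reads = simulate_reads(transcripts, truth, small_config)
    return transcripts, truth, reads


@pytest.fixture(scope="session")
def small_references(small_library):
    transcripts, _, _ = small_library
    return {t.id: t.sequence.replace("U", "T") for t in transcripts}
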