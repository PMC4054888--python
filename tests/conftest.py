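import numpy as np
import pytest

from pare_decay import (
    EndoMotifSpec,
    SimulationConfig,
    simulate_libraries,
    simulate_transcriptome,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small noiseless simulation with planted miRNA and endo structure."""
    config = SimulationConfig(
        n_transcripts=300,
        dispersion=0.0,
        n_mirnas=3,
        n_mirna_targets=6,
        endo_motifs=[EndoMotifSpec("ACGGAUCGU", 8, "both")],
        seed=11,
    )
    annotations, sequences = simulate_transcriptome(config)
    pare, rnaseq, truth = simulate_libraries(config, annotations, sequences)
    return config, annotations, sequences, pare, rnaseq, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
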