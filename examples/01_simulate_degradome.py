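"""Simulate a two-condition degradome with planted truth and write it to disk.

The generator produces PARE signature matrices for an untreated (DW) and a
treated (DC) library, matched RNA-Seq counts (RW/RC), and a ground-truth
record of every planted decay type, miRNA slicing site, and endonuclease
motif — the raw material for every other example.
"""

from pathlib import Path

from pare_decay import (
    EndoMotifSpec,
    SimulationConfig,
    simulate_libraries,
    simulate_transcriptome,
    write_fixture,
)

config = SimulationConfig(
    n_transcripts=500,
    n_mirnas=3,
    n_mirna_targets=8,
    endo_motifs=[EndoMotifSpec("ACGGAUCGU", 8, "DC")],
    dispersion=0.05,
    seed=42,
)
annotations, sequences = simulate_transcriptome(config)
pare, rnaseq, truth = simulate_libraries(config, annotations, sequences)

out = Path("scratch/example_fixture")
manifest = write_fixture(annotations, sequences, pare, rnaseq, truth, out)

print(f"wrote {len(manifest)} files to {out}/")
print(f"DW library: {pare['DW'].total_mapped:,.0f} mapped signature reads "
      f"on {len(pare['DW'].counts)} transcripts")
print(f"planted: {len(truth.mirna_targets)} miRNA slicing sites, "
      f"{len(truth.endo_sites)} endonucleolytic cuts")
# The totals above are what the normalization step equalizes between
# libraries; the planted counts are what the later examples try to recover.
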