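"""Detect endonucleolytic cleavage sites and group them by a shared motif.

Transcripts whose degradome signal is a single dominant spike, not explained
by any miRNA, are candidate endonuclease substrates.  Flanks anchored at the
cut are searched for a shared motif whose 5' end coincides with the cut;
groups smaller than six members are dropped, survivors are labelled by
condition specificity and localized to 5'UTR / CDS / 3'UTR.
"""

from pare_decay import EndoMotifSpec, SimulationConfig
from pare_decay.endo_cleavage import groups_to_frame
from pare_decay.evaluation import endo_recovery, run_standard_analysis

config = SimulationConfig(
    n_transcripts=3000,
    dispersion=0.05,
    endo_motifs=[
        EndoMotifSpec("GAUCGGUA", 10, "DW"),
        EndoMotifSpec("CCGUUAAGG", 8, "DC"),
        EndoMotifSpec("UUCGAGCA", 4, "both"),  # too small: should be dropped
    ],
    seed=9,
)
run = run_standard_analysis(config)

print(groups_to_frame(run.groups).to_string(index=False))
res = endo_recovery(run)
print(f"\nsite recall {res['site_recall']:.2f}, "
      f"precision {res['site_precision']:.2f}; "
      f"{res['n_groups']} groups survive the >=6-member filter")
# The 4-member motif is planted but never reported: the minimum-group-size
# rule removes it before condition labelling.
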