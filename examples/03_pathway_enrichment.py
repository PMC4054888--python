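"""Fisher's exact enrichment of a degradome gene list for pathway target sets.

Genes whose degradation products appear in a PARE library can be tested for
over-representation of the known substrates of each decay pathway
(decapping, deadenylation, NMD, exosome).  Here the "decapping" set is
deliberately built to overlap the detected list and the "exosome" set to
avoid it, so one test comes out enriched and the other does not.
"""

import numpy as np

from pare_decay import TargetSet, batch_enrichment

rng = np.random.default_rng(0)
background = [f"gene{i:04d}" for i in range(4000)]

detected = set(rng.choice(background[:2000], size=900, replace=False))
tdt = TargetSet("TDT_decapping", frozenset(
    list(rng.choice(sorted(detected), size=60, replace=False))
    + list(rng.choice(background, size=28, replace=False))
))
rrp4 = TargetSet("RRP4_exosome", frozenset(rng.choice(background, size=119, replace=False)))

table = batch_enrichment({"DW": detected}, [tdt, rrp4], background)
print(table.to_string(index=False))
# a = genes both detected and in the set; the two-tailed P is exact
# (point-probability method) and the star threshold is P < 0.001.
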