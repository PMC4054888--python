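# Methods

## Data model and coordinates

A PARE library is a sparse signature matrix: transcript → (position →
count), where the position is the 1-based transcript coordinate of the
5'-phosphorylated first nucleotide of a degradome tag — the same convention
5'-RACE uses for cleavage sites, so a cut between bases *p−1* and *p* shows
up as a signature at *p*. Counts are real-valued: a tag mapping to *k*
positions contributes 1/*k* of its reads to each (equal division; no
abundance-weighted scheme, since none is defined for count-level input),
and normalization rescales whole libraries. CDS coordinates are inclusive;
the 5' UTR is `[1, cds_start−1]`, the 3' UTR `[cds_end+1, length]`, and a
cut at a CDS boundary is a CDS cut. Antisense placements and genome-space
mapping are out of scope: inputs are transcript-space placements or
pre-summarized signature tables.

## Read-level processing

Signatures with count ≤ 5 are omitted before any abundance comparison. The
filter is applied per (transcript, position) entry, not per transcript
total, because PARE abundance is a property of the individual signature.
Normalization multiplies the treated library by (reference total mapped
mass) / (target total mapped mass); the totals default to the
transcriptome-mapped mass held in the matrices, and both totals can be
overridden when an external (e.g. genome-mapped) population size is the
desired denominator.

## Decay-type classification

Direction calls are inclusive: up ⇔ log₂FC ≥ t, down ⇔ log₂FC ≤ −t, with
t = 1.5 by default. Fold changes are pseudocounted,
log₂((x+1)/(y+1)), which maps (0, 0) to 0 and keeps every value finite; the
pseudocount is configurable because thresholding raw versus pseudocounted
ratios is a genuinely open choice. The five outcomes (I, II, III, IV,
UNCLASSIFIED) partition the (D, R) plane; type fractions can be reported
over I–IV only or over all five — both denominators are available from the
count vector. The joint table keeps genes with nonzero abundance in at
least one condition on *each* platform ("found in both libraries");
transcripts seen by only one platform are excluded rather than zero-filled.

## Fisher's exact enrichment

The two-tailed P is the point-probability (Fisher–Irwin) sum: over all
tables with the observed margins, the hypergeometric probabilities not
exceeding the observed table's. For hypergeometric supports up to 10,000
values the implementation works in exact integer arithmetic (`math.comb`
numerators over a shared denominator), so tie comparisons are exact and the
result is correct to output float precision; larger supports fall back to
log-gamma arithmetic with a 1e−9 relative tie tolerance. Exact integers
were preferred over a purely log-space implementation because the package's
own validation demands ≤ 1e−12 agreement with exhaustive enumeration, which
log-space rounding near probability ties cannot guarantee. No
multiple-testing correction is applied by default (raw two-tailed P with a
0.001 star is the reporting convention); a Bonferroni option exists.
"Presence in a library" means nonzero post-filter PARE abundance.

## miRNA target detection

Scoring is the de-facto plant small-RNA target scheme: gapless duplex,
mismatch 1, G:U wobble 0.5, penalties doubled at miRNA positions 2–13,
cutoff 4.5 — all constants configurable. The predicted cleavage position is
the transcript base paired to miRNA position 10 (the 5' nucleotide of the
3' fragment), and a candidate window becomes a hit only with ≥ 1 normalized
read at exactly that position in at least one library. Degradome categories
follow the established five-level convention: 0 unique maximum on the
transcript, 1 tied maximum, 2 above the median of nonzero signatures, 3 at
or below the median with more than one read, 4 at most a single read
(fractional normalized counts ≤ 1 fall in category 4). The condition
comparison derives three arrows — miRNA (supplied expression fold change),
mRNA (R fold change), degradation product (normalized site count fold
change) — all at the same inclusive ±1.5 log₂ threshold.

## Endonucleolytic cleavage pipeline

"A single dominant spike" is operationalized as a triple rule on the
filtered, normalized matrix: count ≥ 10, fraction of the transcript's total
signature mass ≥ 0.5, and ratio to the runner-up position ≥ 5. At most one
site is called per transcript and an exact tie for the maximum disqualifies
it — multi-peak transcripts are excluded rather than multiply reported.
Sites within ±2 nt of a miRNA-explained cleavage are removed (positional
jitter of PARE spikes). Flanks of 10 nt upstream and 15 nt downstream are
extracted so that the cut position is a fixed internal offset; the window
is asymmetric because cleavage motifs extend 3' of the cut, which is the
motif's 5' end.

### Motif discovery

The anchored motif finder is self-contained. For each width w (6–12 by
default) it seeds with the most frequent exact w-mer at the anchor, takes
sequences within Hamming distance 1 of the seed, and iterates a PWM
(pseudocount 0.25) / membership loop where a sequence belongs if its
anchored w-mer scores ≥ w bits of log-odds against a uniform background. A
candidate is kept only if every PWM column reaches 1 bit of information
content (this prunes widths that overrun the conserved core into random
flanking sequence). Significance is an E-value: the binomial tail
probability of the observed membership given the background match
probability of the refined PWM (computed exactly by per-column convolution
of the score distribution), Bonferroni-scaled by the 4^w possible seeds. It
is an internal calibration statistic — comparable across runs of this
engine, deliberately not numerically comparable to MEME's E-value. Because
the background match probability is non-monotone in width, the seed width
with the smallest E-value can undershoot the true motif; the reported
consensus is therefore grown column-by-column past the seed width while
each added column keeps ≥ 1 bit of information (3'-only for cut-anchored
motifs, both directions in the scanning mode used for UTR motifs). Each
sequence joins at most one motif; groups below the minimum size (6 members
by default) or above the E-value cutoff (0.001) are dropped. Group
condition labels: control-only if every member site was detected only in
the control library, treated-only symmetrically, otherwise shared.

## Synthetic data generator

The generator emulates a two-condition degradome study: DW/DC PARE
libraries and RW/RC RNA-Seq counts over a random transcriptome
(600–2,000 nt, UTR fractions 0.15/0.25, Poisson(3) introns, uniform ACGU
sequence). Decay types are drawn from a configurable mixture (default
0.2 / 0.35 / 0.15 / 0.2 / 0.1 over I–IV and null, mirroring the reported
ordering in which type II is the largest class and type III the smallest);
changed axes move by ±2.5 log₂ units. Totals are negative binomial with
dispersion α (variance = μ + αμ², default α = 0.05 at mean depth 200 —
free parameters of the simulator, chosen as typical bulk-count
overdispersion, not estimates of any particular dataset); α = 0 is the
noiseless limit in which totals equal their means exactly as floats, so
planted fold changes are exact on raw ratios.

**Mass balance.** Population-size normalization can only preserve planted
per-gene fold changes if the mass gained by up-genes matches the mass lost
by down-genes on each axis. The generator therefore allocates up/down signs
per type — an up gene adds 2^fc − 1 base units, a down gene removes
1 − 2^−fc, so the balanced up-fraction is small (≈ 0.15 at fc = 2.5) — via
a feasibility search over the type-I split that respects the coupling of
the D and R axes through types I (together) and III (apart). Residual
imbalance is below one gene's mass, i.e. a ≲ 0.001 log₂ shift at n = 10⁴.
Mixtures for which the coupling makes exact balance impossible (e.g. pure
type III) retain a compositional shift, exactly as a real experiment
normalized by total library size would.

**Positional placement.** A planted event (miRNA slicing or endonuclease
cut) receives `peak_fraction` (default 0.9) of the transcript's reads at
the cut; the remainder — and all reads of event-free transcripts — is
split deterministically over ~20 randomly placed positions with 5'-biased
rank-geometric weights (rate 0.15). The maximal background share of any
one position is ≈ 0.16 of the scattered mass, so background can never
satisfy the prominence rule, while positional conservation (positional
sums equal the drawn total) holds exactly. Stochasticity lives in the
totals and in the position draw, not in the split. miRNA target windows
are exact reverse complements written into CDS regions; endonuclease
consensi are written with the cut at their 5'-most base, placed in
5'UTR/CDS/3'UTR with weights 0.05/0.40/0.55 (the approximate regional
distribution reported for such cleavages). Sequence planting overwrites
the passed sequence mapping in place; each transcript hosts at most one
event, so occurrences cannot collide.

**What the generator does not emulate:** read-level errors and quality,
poly(A)-tail length dynamics and deadenylation loss (tags are abstracted
to position counts), ncRNA contamination, genome-space multimapping
structure, and biological correlation between decay type and sequence
features. Passing recovery tests therefore demonstrates the correctness of
the analysis logic under the stated noise model, not performance on real
libraries.

## Validation scale and determinism

The packaged validation runs at desk scale on one CPU: 10,000 transcripts
for classification recovery (noiseless, and five seeds at dispersion 0.05),
an exhaustive sweep of all ~6.4×10⁵ contingency tables with N ≤ 60 for the
Fisher statistic, 1,000 null draws for enrichment calibration, 2,000
transcripts with 20 planted slicing events, and 5,000 transcripts with
three planted cleavage groups plus an undersized decoy. All randomness
flows from explicit integer seeds through `numpy.random.default_rng`;
identical config and seed give byte-identical outputs, including fixture
checksums.

## Known limitations

- The prominence triple and the motif window are declared operational
  choices; other thresholds are defensible and all are exposed as
  configuration.
- The motif E-value is calibrated for the engine's own null (uniform
  background, anchored or single-occurrence scanning); sequences with
  strong compositional bias would need a background model the engine does
  not fit.
- Up/down sign allocation in the simulator is asymmetric by necessity (see
  mass balance); per-direction subgroup sizes are therefore unequal.
- GFF3 ingestion requires exon features to project CDS coordinates into
  transcript space; annotations without exons must be supplied as TSV.
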