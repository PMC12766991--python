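# Methods

## The problem

Combinatorial barcoded-Tn5 library preparation labels each sample's
pre-amplified full-length cDNA with a pair of 8-nt indices carried on the
two Tn5 adapter species (A and B).  Because every sequenceable fragment
receives one A end and one B end, *m* A-reagents and *n* B-reagents
address *m*·*n* samples; ten of each address 100.  The B adapter
additionally carries a 6-nt random UMI that tags each tagmentation
fragment, so unique-UMI counting collapses PCR duplicates and quantifies
fragments rather than reads.  `cbtiseq` implements the computational side
of this design — simulation with per-fragment ground truth, combinatorial
demultiplexing, fragment-UMI quantification and full-length QC — so the
decoding pipeline can be built and verified entirely on synthetic data.

## Read architecture and restructuring

Read 1 is `[barcode A (8)] [mosaic end (19)] [insert]`; read 2 is
`[barcode B (8)] [UMI (6)] [mosaic end (19)] [insert]`, the two inserts
reading toward each other from the fragment's two ends.  The read-2
technical prefix is therefore 8 + 6 + 19 = 33 nt.  The decoder mirrors the
published preprocessing exactly: barcode B and the UMI are moved to the
front of read 1 and the 33-nt prefix is deleted from read 2; tag
extraction on the raw and restructured layouts is equivalent (tested).
The canonical 19-nt Tn5 mosaic end `AGATGTGTATAAGAGACAG` is the default
and is configurable.

## Whitelist design

Whitelists are generated by seeded greedy randomized search under four
constraints: length 8, pairwise Hamming distance ≥ 3, GC fraction in
[0.25, 0.75], homopolymer runs ≤ 3.  The distance floor of 3 is what makes
unique-nearest-neighbour correction at Hamming distance 1 sound: the
distance-1 balls around distinct barcodes cannot intersect.  Because both
barcodes are read in 8-cycle windows, the A and B lists are additionally
validated as a union (a corrupted B barcode must never be correctable to
an A barcode); `generate_barcode_set(..., exclude=...)` builds the second
list against the first.  The search caps attempts per code and raises a
design-infeasibility error rather than returning a short set.

## The simulator's tagmentation model

Each transcript template is the transcript sequence plus a poly(A) tail
(default 90 nt).  Fragment lengths follow a truncated normal — mean
400 nt, sd 75 nt, bounds [150, 800] — matching the observed 300–500 bp
tagmentation product range.  Fragment *placement* models a uniform
tagmentation cut density: the start is drawn uniformly over every position
at which the fragment overlaps the template (the extended range
`[-(L-1), T-1]`), and the fragment is clipped at the template ends.  Under
this model every template base is covered with equal probability, so the
simulator is an exactly flat null for the gene-body-coverage metric.
Clipped products shorter than `min_fragment_length` (default 30 nt) are
redrawn, mimicking bead size selection.

Two deliberate simplifications follow from this choice.  First, terminal
fragments are treated as sequenceable even though in the real chemistry a
molecule-end fragment lacks one Tn5 adapter and drops out of indexing PCR;
real libraries therefore dip in coverage near transcript termini in a way
this simulator intentionally does not.  Second, reads derived from clipped
fragments pile up at template ends, so with few transcripts the per-base
composition of insert positions reflects the transcript end sequences
rather than an i.i.d. null.  Passing coverage-flatness tests consequently
certify the metric and the placement model, not the end behaviour of real
libraries.

3'-degradation is modelled by reweighting placement with
`exp(delta * relative_position)`; `delta = 0` is uniform and increasing
`delta` shifts mass toward the poly(A) end, which the 3'/5' bias index
tracks monotonically (tested at delta in {0, 1, 2}, three seeds).

Pooling is multinomial — each fragment's sample is uniform over the sheet
— so per-sample depths fluctuate binomially exactly as molecules drawn
from an equimolar pool do.  Per-sample transcript abundances are
log-normal (sigma = 1, renormalised).  Only A–B fragments are emitted
(A–A and B–B products do not amplify in indexing PCR); the adapter end
carrying A is chosen with probability 1/2 per fragment.  The 9-bp Tn5
target-site duplication is not modelled: it is invisible at the
read-structure level the decoder sees.  Substitution errors are i.i.d. at
the configured rate (default 0.002/base when enabled; error positions get
Q14, all other bases Q37, Phred+33).  Reads that run past the library
molecule continue into the opposite adapter (reverse-complement mosaic
end, UMI, barcode) and then a constant downstream flank, which is exactly
what the read-through trimmer removes.

## Decoding and correction

Per pair: restructure → extract tags → correct each barcode
(unique-nearest-neighbour, max distance 1; ties and distances > 1 are
unassigned; any N counts as a mismatch and > 2 N in a barcode is
unassigned outright) → quality-filter tag bases (all ≥ Q10) → sample-sheet
lookup.  Valid (A, B) pairs absent from the sheet are tallied as
`pair_not_in_sheet`, a cross-contamination diagnostic.  Every pair gets
exactly one outcome and the outcome counts must sum to the input count;
`DemuxStats.validate()` enforces this on every run.  UMIs are never
error-corrected: with 4096 states, collapsing near-neighbours would merge
genuinely distinct fragments.  The cDNA insert carried forward is the
restructured read 2 after read-through trimming (leftmost occurrence of
the reverse-complement mosaic end, ≤ 1 mismatch, or an exact terminal
partial match ≥ 8 nt) and poly(A) trimming (longest 3' suffix ≥ 6 nt
starting with A and containing ≤ 1 non-A).  The read-1 insert is retained
behind `DemuxConfig.keep_r1_insert` (default off, matching the convention
of tagging and aligning the cDNA mate only).

## Transcript assignment and UMI counting

A forward-strand exact 21-mer index over the transcriptome stands in for
a genomic aligner at desk scale; the reverse strand is matched by querying
the reverse complement of the insert.  Votes are pooled per (gene,
strand); the winner needs ≥ 3 votes and more than twice the runner-up,
else the read is ambiguous; the mapped interval comes from the modal
k-mer diagonal.  Inserts shorter than k are `too_short` by contract.

Deduplication policies: `umi` counts distinct (sample, gene, UMI) triples
— strict digital-expression semantics — while the default `umi_pos` adds
the fragment start rounded to 10 nt, because a 6-nt UMI collides quickly
within a deeply covered gene and the UMI labels a *fragment*, which has a
position.  With simulator UMIs drawn without replacement per (sample,
gene) (`SimConfig.unique_umis`), error-free deduplicated counts equal
ground-truth fragment counts exactly; with replacement they undercount by
the birthday-collision rate, which is the realistic behaviour.  Saturation
curves use nested subsampling (one uniform draw per read), making
detection monotone in depth for a fixed seed.

## QC metrics

Gene-body coverage projects each fragment interval onto 100 percentile
bins of its transcript (clipped to the transcript body, so poly(A)
overhang does not contribute), normalises each transcript's profile to
unit mass, and averages over transcripts of length ≥ 500 nt.  The bias
index is the mean of bins 80–99 over the mean of bins 0–19: 1.0 for a
flat profile, +inf when the 5' quintile is empty.  Species-mixing calls
use UMI counts: a sample is MIXED when strictly more than 20% of its
counts belong to the minor species (the boundary 20% keeps its
major-species call, reading the rule literally as "more than 20%");
zero-count samples are UNDETERMINED.

## Numerical and interface choices

Coordinates are 0-based half-open on the polyadenylated template
throughout.  All randomness flows from `numpy.random.default_rng` seeds;
the pipeline derives stage seeds from one root seed, and rerunning with
the same seed reproduces byte-identical artifacts (tested).  Problem
sizes in the test and acceptance runs (tens of thousands of pairs,
20–30 transcripts of ~2 kb) were chosen to give the binomial oracles
adequate power while keeping a full run in well under a minute each.
Standard formats go through standard libraries (Biopython for
FASTA/FASTQ, scipy for MatrixMarket, pandas for tables); the ground-truth
TSV and whitelist text formats are package-defined and parsed with
line-numbered error reporting.

## Known limitations

No indels, no PCR chimeras, no template-switching artifacts, no
intron/nascent reads, no index hopping, no B-end-only (oligo-dT-primed)
fragments.  The k-mer voter has no mismatch tolerance inside a k-mer, so
at high substitution rates mapping rates fall faster than a real aligner's
would.  Coverage flatness at delta = 0 is exact by construction of the
placement model, not evidence about end-capture efficiency in real
libraries.
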