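# Methods

## The homodimer error-detecting code

Barcodes (12 blocks, 24 nt) and UMIs (8 blocks, 16 nt) are synthesized
from dimeric nucleotide building blocks, so a correctly sequenced
position reads as two identical bases. "Complementarity" throughout this
package means identity of the two bases within a block — a property of
the homodimer chemistry — not Watson–Crick pairing. A block is valid iff
its bases are equal and neither is `N`; `N` is never collapsible. Both
barcode and UMI use the same `DimerSequence` type; block counts are
configuration, not constants.

Under an independent per-base error model with survival probability
*p*, a read of *l* bases is fully complementary with probability *p^l*,
so the observed perfect-complementarity fraction *b* implies a per-base
accuracy of *b*^(1/*l*) (`theoretical_accuracy`). The *measured*
accuracy counts erroneous bases directly: each invalid block contributes
a configurable number of erroneous bases, default 1, because a single
substitution suffices to break a pair. The weight is configurable to 2
for sensitivity analysis — with real data one cannot distinguish one
broken base from two, and the choice shifts the measured (not the
theoretical) accuracy by exactly the invalid-block density.

## Read extraction

A capture read is handle (25 nt, `AAGCAGTGGTATCAACGCAGAGTAC`) + barcode
(24) + UMI (16) + poly(T) + cDNA, in either orientation. The handle is
located by approximate substring match (edlib, infix mode) with at most
3 edits by default — roughly the nanopore error expectation on a
25-mer. The poly(T/A) tract is found by a sliding window of
`polyT_min_len` (default 15) bases that must *start and end* with the
homopolymer base and may contain at most 1 interior mismatch per 10
bases. The endpoint condition is deliberate: a window spanning a 14-base
run plus one adjacent foreign base would otherwise pass a 15-base
threshold on the mismatch budget alone, making the minimum-length
parameter meaningless at the boundary. When both orientations parse,
the one with fewer handle edits wins; exact ties keep the forward
orientation. Coordinates are 0-based, half-open. Extraction emits
UMI-tools-style headers (`readid_BARCODE_UMI`) so downstream alignment
preserves the cell/UMI annotation. Indel-aware block realignment is out
of scope: errors inside the barcode/UMI segment are handled downstream
by edit-distance matching, not by re-segmenting the read.

## Two-pass barcode correction

Pass one trusts reads whose 12 blocks are all valid, collapses them to
12-mers, merges duplicates (counts summed) and keeps the
`expected_cells` most abundant (default 1000, matching the fixed
set-cell-number style of cell selection; knee-point calling is a
non-goal). Pass two matches every remaining read's *raw 24-mer dimer*
barcode against the whitelist representatives by Levenshtein distance,
assigning the unique nearest entry within `max_edit` (default 6 for
long reads, 4 for short-read-quality input). Matching in dimer space is
essential: the redundancy of the dimer encoding is what separates true
barcodes (mutual distances typically ≥ 12) from their error clouds, and
edit distances of 4–7 only make sense against the 24-mer. Ties at the
minimal distance are left unassigned — conservative, because aggressive
assignment inflates cross-species contamination in mixed-species
controls. The matcher is an exhaustive scan with edlib's banded
early-exit (`k = max_edit`); results for identical observed barcodes are
cached, so the perfect-read majority costs one lookup.

## UMI deduplication

UMIs with all blocks valid collapse to one 8-mer; UMIs with any invalid
block are split into their two strands (first bases of each block /
second bases), each collapsed to an 8-mer candidate. Candidates
containing `N` are dropped. Candidates are pooled with weight 1 and
clustered with the directional network rule of UMI-tools: edge A→B when
Hamming distance is 1 and count(A) ≥ 2·count(B) − 1; traversal seeds
visit nodes in descending count with lexicographic tie-break, which
makes clustering deterministic. Hamming (not Levenshtein) distance is
the UMI convention on equal-length 8-mers.

Counting molecules needs one step beyond cluster counting. Each read is
one molecule, but a split read contributes two candidates; at a 10%
per-base error rate about a third of erroneous reads produce a stray
candidate two or more blocks away from the truth, and counting raw
clusters would overestimate molecule numbers severalfold. The counting
layer therefore (i) assigns every read to the best-supported cluster
among its candidates, and (ii) rescues clusters supported by only a
single split read into the most-supported cluster whose representative
is *consistent* with that read. Consistency is exact, not heuristic: a
substitution changes one base of a block, so at every invalid block the
true base must be one of the two observed bases; a representative
agreeing with one of the two candidates at every position is a valid
origin for the molecule, and a chance match by an unrelated 8-mer has
probability ≤ (1/2)^m (1/4)^(8−m) for m invalid blocks. The estimate is
the number of clusters with at least one read assigned after rescue.
In simulation at the study conditions this brings the mean relative
bias of the molecule count from roughly +10% (assignment only) or
+100–300% (raw cluster counting) to within a few percent of zero.
`directional_dedup` itself remains the unmodified directional method,
so it can be checked against brute-force clustering directly.

Per-cell counting groups records by (cell, feature), deduplicates each
group, and drops cells expressing fewer than `min_features` features
(default 200). Features are transcript-level alignment targets; the
counts are written as an MTX triplet.

## Simulators

The simulators define the study conditions and generate all validation
data; their defaults are fixed, not tuning knobs.

**Barcodes.** True barcodes are random distinct dimer 24-mers; each is
read `depth` times (default 400). A 95% share of *reads* (per read, not
per barcode — this keeps an error-free first-pass pool for every
barcode, which is what a 5% verbatim-copy rate produces) is eligible
for substitution errors. PCR errors (rate 1e-5 per base per cycle,
25 cycles) are folded into an effective per-base probability
1 − (1 − p)^cycles, since a sampled molecule has passed through about
that many replications; at the default rates this adds ~2.5 × 10⁻⁴ to
the sequencing error and is negligible next to it. Errors are uniform
substitutions over the three alternative bases; indels are not
simulated.

**UMIs.** A pool of distinct dimer 16-mers, each with an amplification
probability drawn uniformly from [0.8, 1.0]. Per cycle, every molecule
duplicates with its probability; PCR errors mutate the copy, and a
mutated copy receives a fresh amplification probability. The final pool
is subsampled *without replacement* to the sequencing depth (requesting
more than the pool exists warns and returns the whole pool), then
per-base sequencing errors are applied. Every molecule carries its
founder's identity, so the truth map survives PCR errors exactly.

**Full reads.** For end-to-end tests, a generator writes gzipped FASTQ
of handle + barcode + UMI + poly(T) + random cDNA in both orientations
plus a truth table. Quality strings are constant placeholders; real
nanopore indel/homopolymer error profiles are not emulated. Passing
tests on these reads therefore demonstrates the logic of segmentation
and correction under substitution noise, not robustness to nanopore
indel artifacts — on real data the extraction rate is expected to be
lower, which affects yield, not correctness of what is extracted.

All generators are deterministic under a fixed seed (gzip members are
written with zeroed timestamps so that reruns are byte-identical).

## Fusion calling

Primary alignments are filtered with flag mask 3328 (secondary 256 +
duplicate 1024 + supplementary 2048); chimeras are primaries carrying an
SA tag, parsed per the SAM specification with positions converted to
0-based half-open and reference spans computed from the CIGAR. Loci map
to genes by maximal overlap against a BED interval index; ties are
ambiguous and dropped, as are intergenic loci and same-gene (exonic)
chimeras. By default only the first supplementary locus is paired with
the primary; multi-segment chimeras can emit all pairwise candidates
behind a flag. Events are identified by the *unordered* gene pair —
the breakpoint orientation is retained as metadata but counting is
pair-level. Support is the sum over cells of deduplicated UMI counts,
and events below `min_fusion_umis` (default 5) are removed; in a
mixed-species control, where cross-species fusions are impossible, this
threshold empties the cross-species class, which is the calibration
argument for applying it to single-species data. Gene positional
metadata is emitted as TSV columns rather than bespoke SAM tags.

## Pipeline and QC

Stages communicate through files (FASTQ/SAM/TSV/MTX), so each is
independently re-runnable; a stage failure raises a stage-tagged error
and leaves earlier outputs in place. The QC JSON records the verbatim
config with a hash and the tool version, plus: poly(A) detection rate,
parse rate, perfect-complementarity fraction *b*, theoretical accuracy
*b*^(1/24), measured accuracy, assignment fractions (perfect +
corrected + unassigned = 1), whitelist size, and cells passing the
feature filter. The barnyard summary classifies cells by UMI purity
(dominant species share); the threshold defaults to 0.9 — plots in this
field rarely state a cutoff, and 0.9 separates the visually pure arms
of a two-species plot while flagging clear doublets.

## Problem sizes and numerical choices

Validation runs are sized for a single CPU: barcode recovery at 500
barcodes × depth 50 × 5 replicates in tests (about two minutes), and
200 × 50 × 3 in the acceptance script; UMI bias over ≥100 replicates
across 10/50/100 true UMIs at depth 400 with 4–12 cycles. Depth 400 is
used for the bias property because an estimator cannot recover more
molecules than reads sampled; depths below the molecule count measure
sampling loss, not deduplication error. These sizes are the package's
validation choices; the same code runs at the full study scale
unchanged. Random UMI draws at n ≤ 100 in a 4⁸ space collide with
probability under 10%, and founders are drawn distinct so the ground
truth is exact.

## Known limitations

- Substitution-only error model; no indel or homopolymer simulation.
- Whitelist selection is rank-based; no knee-point or ambient-RNA
  modelling.
- Split-candidate rescue assumes at most one substitution per block;
  blocks with both bases wrong defeat the consistency test and can
  leave a small positive bias at high error rates.
- Dataset-scale headline statistics of the original study (observed
  complementarity fractions, cell yields, fusion catalogues) require
  the full sequencing data and are outside desk-scale validation.
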