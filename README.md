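# dimerseq

Error detection and correction of homodimer-encoded cell barcodes and UMIs
in noisy long-read single-cell RNA sequencing.

## The problem

Nanopore sequencing reads full-length transcripts but with a 5–15% error
rate, which scrambles the short cell barcodes and unique molecular
identifiers (UMIs) that single-cell protocols rely on: reads cannot be
assigned to cells, and PCR copies cannot be collapsed into molecules.
One synthesis-level remedy is to build the barcode and UMI from *dimeric*
nucleotide blocks, so that every position appears as two identical
consecutive bases (`AA`, `CC`, `GG`, `TT`). Any within-block disagreement
flags a sequencing error read-by-read, without a reference whitelist.
`dimerseq` implements the computational side of that design for
bioinformaticians processing such libraries:

- **dimer core** — block validity, collapse/expand between dimer (2*l*)
  and monomer (*l*) space, and base-calling accuracy estimators. If *b*
  is the fraction of reads with perfect block complementarity over an
  *l*-nt barcode, the implied per-base accuracy is *b*^(1/*l*).
- **extraction** — locating the PCR handle, 24-nt barcode, 16-nt UMI and
  poly(T) tract in either read orientation.
- **two-pass barcode correction** — a whitelist built from reads with
  perfect complementarity, then rescue of erroneous barcodes by bounded
  Levenshtein matching (edit distance 6 by default for long reads).
- **UMI deduplication** — erroneous UMIs are split into their two block
  strands, collapsed to 8-mers, and counted with the directional network
  rule (edge A→B when Hamming distance is 1 and
  count(A) ≥ 2·count(B) − 1), with a read-aware layer that keeps split
  candidates from inflating molecule counts.
- **per-cell counting** — a sparse feature × cell matrix (MTX triplet)
  with a minimum-features cell filter.
- **fusion calling** — chimeric reads from SA tags, gene assignment from
  a BED interval index, and a ≥5-UMI support filter calibrated so that
  impossible cross-species events vanish in a mixed-species control.
- **simulators** — barcode PCR/sequencing error simulation and UMI
  amplification simulation with exact ground-truth tracking, used for
  all validation.

## Worked example

Simulate dimer barcodes at the study conditions (24-nt barcodes, PCR
error 1e-5 over 25 cycles, 95% of reads error-eligible) and measure how
many reads the two-pass correction returns to their true barcode:

```python
from dimerseq import BarcodeSimParams, recovery_curve, theoretical_accuracy

p = BarcodeSimParams(n_barcodes=100, depth=50, seed=0)
print(recovery_curve([0.0, 0.05, 0.10, 0.15], p, edit_distance=6, replicates=3))
print(f"{theoretical_accuracy(0.68, 24):.4f} {theoretical_accuracy(0.129, 24):.4f}")
```

```
 error_rate  fraction_recovered       se
       0.00            1.000000 0.000000
       0.05            0.999933 0.000067
       0.10            0.983133 0.006360
       0.15            0.883933 0.012849
0.9841 0.9182
```

At a 10% per-base sequencing error rate, 98.3% of reads are still
assigned to the correct cell; recovery degrades gracefully beyond that.
The two closed-form numbers are the per-base accuracies implied by
perfect-complementarity fractions of 0.68 (98.4%, typical of short-read
data) and 0.129 (91.8%, typical of nanopore data).

The same workflow is exposed as a CLI:

```bash
dimerseq simulate reads --n-cells 20 --reads-per-cell 20 \
    --fastq reads.fastq.gz --truth truth.tsv --seed 1
dimerseq extract reads.fastq.gz --out extracted.fastq.gz
dimerseq correct extracted.fastq.gz --edit-distance 6 --expected-cells 20 \
    --whitelist-out whitelist.tsv --assignments-out assignments.tsv
dimerseq count alignment.bam --per-feature-tag XT --min-features 200 --out counts/
dimerseq fusion alignment.bam --bed genes.bed --min-umis 5 --out fusions.tsv
dimerseq run --config run.yaml   # full pipeline + QC JSON
```

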