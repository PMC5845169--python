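# plateseq

A toolkit for plate-based, cell-barcoded single-cell RNA-seq processing and
statistics:

- **barcodes** — design of error-correcting DNA cell barcodes under a
  boundary-minimum edit distance (indels shift the downstream read frame, so
  trailing truncations are free). A minimum pairwise distance of 5 guarantees
  unique correction of up to two substitutions, insertions or deletions.
  Candidate codes are grown by seeded greedy closure and a subset is selected
  to balance pooled base composition.
- **demux** — read-structure parsing (Read1 = cell barcode + 8 nt UMI,
  Index1 = 6 nt pool barcode, Read2 = cDNA), barcode correction of up to two
  edits with indel-aware UMI relocation, quality filtering, and pool
  demultiplexing.
- **counting** — UMI collapse (exact or Hamming-1 single-linkage) into a
  genes × cells digital expression matrix, read counting, cell filtering by
  detected genes, depth normalisation (target 10,000 or mean total), natural
  log transform and per-gene z-scaling. MatrixMarket triplet and TSV I/O.
- **qc** — UMI conversion efficiency (UMI counts over initial fastq reads,
  per cell), spike-in capture efficiency (through-origin regression of
  detected UMIs on input molecules), and the input copy number at 50%
  detection probability (per-cell Bernoulli logistic fit).
- **degs** — differential expression by the difference in deviance between
  nested count GLMs (Poisson with log total-count offset by default,
  negative binomial optional), with a fold-change-2 pseudocount prefilter
  and Benjamini–Hochberg correction; exact binomial cluster-marker tests.
- **cellcycle** — classification of within-cell-type variable genes into
  cell-cycle-associated and less-associated classes using DNA-stain
  intensity rank bins (default 40) and z-scaled coefficients of variation.
- **simulate** — ground-truthed synthetic data: NB expression with planted
  DE and cell-cycle programs, spike-in capture, PCR-duplicated reads with
  injected barcode errors, byproduct reads, and a flow-cytometry table.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (barcode-design
counts and distances, correction radius, conversion-efficiency bookkeeping,
capture-efficiency recovery, DEG-test calibration, cell-cycle recovery, and
the end-to-end zero-noise identity).

## CLI

```sh
plateseq design --length 14 --min-dist 5 --n 384 --seed 1 --out barcodes.tsv
plateseq verify --barcodes barcodes.tsv
plateseq simulate --cells 96 --genes 200 --seed 1 --out simdir/
plateseq demux --r1 simdir/R1.fastq --r2 simdir/R2.fastq --i1 simdir/I1.fastq \
    --barcodes simdir/barcodes.tsv --out demuxdir/
plateseq count --tagged simdir/tagged.tsv --collapse hamming1 --out matrix/
plateseq normalize --matrix matrix/ --min-genes 10 --target 10000 --out norm.tsv
plateseq qc --matrix matrix/ --initial-reads 100000 --ercc ercc.tsv --out qc.json
plateseq deg --matrix matrix/ --clusters clusters.tsv --a 0 --b 1 --out deg.tsv
plateseq markers --matrix matrix/ --clusters clusters.tsv --cluster 0 --out markers.tsv
plateseq cellcycle --matrix matrix/ --flow simdir/flow.tsv --bins 40 --z 2 --out cc.tsv
```

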