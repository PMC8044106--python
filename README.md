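# sporetrace

Barcode-based multi-strain competition analysis for serial-transfer
experiments with a sporulation bottleneck.

A panel of 79 strains (wild type, 12 single- and 66 double-deletion
genotypes over a 12-locus regulatory family) is tagged with unique 12-nt DNA
barcodes and competed over nine reinoculation cycles in which only
heat-resistant spores seed the next culture. `sporetrace` provides every
computational stage of that experiment:

- **`sporetrace.synth`** — builds the strain panel, generates
  Hamming-separated barcode libraries, simulates the
  growth → sporulation → heat-kill → multinomial-bottleneck cycle forward
  in time, and renders tagged, error-bearing paired-end FASTQ reads with a
  ground-truth sidecar.
- **`sporetrace.barcode_io`** — demultiplexes read pairs by inline 5-nt/7-nt
  sample tags (exact matching, 48-plex) and assigns strains by exact
  full-length barcode occurrence on either mate; pairs hitting multiple
  barcodes are excluded as ambiguous.
- **`sporetrace.dynamics`** — frequency trajectories, persistence against
  the 1/79 input threshold, and detection of "winner" strains above 25%.
- **`sporetrace.fitness`** — relative fitness
  `W_A = [ln(CFU_A_48h)/ln(CFU_A_start)] / [ln(CFU_B_48h)/ln(CFU_B_start)]`
  and sporulation fitness
  `SF_A = [spores_A_48h/(cells+spores)_A_start] / [spores_B_48h/(cells+spores)_B_start]`
  from CFU plate counts, the permissive/selective plate subtraction, and
  log10 one-sample t-test inference with a Shapiro–Wilk normality gate.
- **`sporetrace.stats`** — single-factor Euclidean PERMANOVA implemented
  from first principles (permutation p-values, exhaustive mode for small n),
  scaled PCA, Spearman initial-vs-final correlation with BH/Holm adjustment,
  and the 16-h optical-density growth increment.

## Test

```sh
python -m pytest tests/
```

The suite includes property tests (conservation, reciprocity, oracle
equivalence against brute-force implementations) and
`tests/test_acceptance.py`, one test per acceptance criterion.

## CLI

```sh
# synthetic run: 24 samples (4 mixes x 6 replicates), reads + ground truth
sporetrace simulate --out run/ --seed 1 --cycles 9 --depth 10000 --error-rate 0.001

# demultiplex + count barcodes
sporetrace count --r1 run/r1.fastq --r2 run/r2.fastq \
    --barcodes run/barcodes.tsv --samplesheet run/samplesheet.tsv --out run/counts

# frequencies, persistence, winners at a transfer
sporetrace dynamics --counts run/counts.counts.tsv --summary run/counts.summary.tsv \
    --samplesheet run/samplesheet.tsv --out run/dyn --transfer 9

# fitness from a CFU competition table
sporetrace fitness --table competitions.tsv --mode ancestor-vs-wt --out fitness.tsv

# statistics
sporetrace stats permanova --frequencies run/dyn.frequencies.tsv --factor mix --n-perm 999
sporetrace stats pca --frequencies run/dyn.frequencies.tsv --out scores.tsv
sporetrace stats spearman --initial initial.tsv --finals finals.tsv --out rho.tsv
sporetrace stats growth --table growth.tsv --horizon-min 960 --out increments.tsv
```

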