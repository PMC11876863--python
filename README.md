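# ribomics

Multi-omics analysis toolkit for matched RNA-seq, Ribo-seq (ribosome
profiling) and TMT-style proteomics experiments, driven by a synthetic-data
generator with planted ground truth so that every stage is testable without
external data.

## What it does

- **`ribomics.synthio`** — simulates matched count/intensity matrices for a
  two-condition design (negative-binomial counts with per-sample size
  factors, log-normal protein intensities) with per-gene effects planted on
  the mRNA, translation-efficiency (TE) and protein channels; simulates
  transcript-coordinate ribosome footprints with per-codon pause
  multipliers; emits localisation/druggability annotations and GMT gene-set
  collections including a positive-control set.
- **`ribomics.normde`** — median-of-ratios size-factor normalization
  (geometric-mean pseudo-reference `R_i`, per-sample factors
  `S_j = median_i(I_ij/R_i)`, normalized values `N_ij = I_ij/S_j`), feature
  filtering (all-zero removal; completeness rule for proteomics), Welch
  t-tests on log2 normalized values, and Benjamini–Hochberg adjustment.
- **`ribomics.ribo`** — P/A-site assignment from footprint 5′ ends, library
  QC (read-length histogram, 5′UTR/ORF/3′UTR/other fractions), per-sample
  log2 TE (normalized RPF over normalized mRNA), differential-TE testing,
  regulatory classification (exclusive / intensified / buffered / forwarded),
  codon occupancy at the A/P sites, and per-codon pause scores.
- **`ribomics.enrich`** — preranked GSEA (weighted running-sum ES, gene-label
  permutation null, NES, BH over sets) and hypergeometric overrepresentation
  with set-size bounds and a detected-gene background.
- **`ribomics.integrate`** — five-group mRNA/protein concordance
  stratification, localisation subcategories (SP/TM/IC/SPTM), GO-term
  membership cross-checks, druggable-proteome overlap summaries, and Ward
  hierarchical clustering (Euclidean or 1−Pearson distance).
- **`ribomics.cli` / `ribomics.pipeline`** — a `ribomics` command with
  subcommands `simulate`, `de`, `te`, `dteg`, `qc`, `codon`, `pause`,
  `gsea`, `ora`, `integrate`, `cluster` and `run` (full pipeline with a
  JSON manifest of seeds, config hash and output checksums).

All file formats are plain text: TSV matrices (first column = feature id,
header = sample ids, `#` comments before the header, `.` for missing), GMT
gene sets, FASTA transcript sequences, and TSV transcript models /
footprints.

## Statistical contract

Both omics layers are tested with the same engine: a two-sided Welch t-test
on log2 size-factor-normalized values with BH correction (q < 0.05 by
default). RNA-seq differential expression in the original study used a
negative-binomial GLM with shrunken fold changes; this package deliberately
applies the Welch-on-log2 engine to both layers for symmetry and reports
unshrunk log2 fold changes. GSEA rankings therefore use unshrunk log2FC.
Per-gene Welch tests at small replicate counts have markedly less power
than shared-dispersion GLMs; simulation-based recovery tests in
`tests/` document the dispersion regimes where planted effects are
recoverable.

## CLI quick start

```sh
# full synthetic pipeline into ./demo
ribomics run --seed 1 --outdir demo

# differential abundance on files
ribomics de --matrix demo/rna_counts.tsv --conditions demo/conditions.tsv \
    --out rna_de.tsv

# preranked GSEA of the result
ribomics gsea --de rna_de.tsv --gmt demo/gene_sets.gmt --nperm 1000 \
    --seed 1 --out gsea.tsv
```

Exit codes: 0 success, 2 validation error, 3 stage failure.

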