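# compseq

Competitive internal-standard amplicon sequencing toolkit: an end-to-end,
reproducible pipeline from simulated targeted multiplex amplicon reads to a
cross-validated transcript-abundance risk classifier.

The pipeline has six stages:

1. **simulate** (`compseq.simulate`) — synthetic cohort generator: subjects
   with demographics and dual 8-nt barcodes, an assay manifest (68 assays
   over 33 genes by default; one reference ACTB assay), true abundances from
   a latent-factor log10 Gaussian model, Poisson molecule sampling and
   binomial NT/IS read splitting, and optional paired FASTQ emission with
   substitution errors.
2. **demux** (`compseq.demux`) — paired FASTQ to per-subject, per-assay
   NT/IS read counts: read joining, dual-barcode demultiplexing,
   primer-based locus assignment, and edit-distance allele classification.
   Every input read pair is counted exactly once.
3. **quantify** (`compseq.quantify`) — NT molecules from the NT/IS read
   ratio times the known spike-in copies (600 per target, 6000 for ACTB);
   abundance as molecules per 1e6 ACTB molecules; per-measurement QC by the
   closed-form stochastic-sampling CV (`CV = -1 + 10^(M^-0.54 + R^-0.54 -
   (M*R)^-0.54)`, fail at CV >= 1.0); assay filter (> 30% missing) and
   subject filter (< 6 measured assays); log10 transform.
4. **impute** (`compseq.impute`) — multiple imputation by chained equations
   with predictive mean matching (proper Bayesian parameter draws, k-donor
   matching) producing M completed copies, plus Rubin's-rules pooling.
5. **classify** (`compseq.classify`) — correlation-adjusted t (CAT) score
   ranking with analytic shrinkage, vote-based feature selection across
   imputed copies (vote fraction >= 60%), per-copy pooled-covariance LDA
   with stratified 10-fold CV, model-size search by average AUC, pooled
   AUC/accuracy/sensitivity/specificity/PPV/NPV, ROC, operating point at
   95% target sensitivity, and a paired-bootstrap model comparison.
6. **cli** (`compseq.cli` / `compseq.cohort_stats`) — orchestration with
   per-stage provenance records, plus cohort summary statistics (Student's
   t-tests and exact Fisher tests by hypergeometric enumeration).

## Command line

```bash
# full synthetic run: simulate -> demux -> quantify -> impute -> train ->
# summarize; artifacts and provenance JSON land in the output directory
compseq run-all --outdir runs/demo --seed 11

# individual stages (share the same outdir)
compseq simulate --outdir runs/demo --seed 11
compseq quantify --outdir runs/demo
compseq train    --outdir runs/demo

# custom configuration
compseq run-all --config my_config.yaml
```

A YAML config can override any stage (see `compseq.cli.DEFAULT_CONFIG`),
e.g.:

```yaml
seed: 11
outdir: runs/demo
simulate:
  n_subjects_cancer: 58
  n_subjects_control: 57
  emit_fastq: true      # otherwise counts come from the simulator tally
impute:
  m_copies: 50
train:
  mode: honest          # selection recomputed inside each CV fold
```

Outputs include `counts.tsv`, `abundance.tsv` (log10 molecules per 1e6
ACTB, "NA" for missing), the imputed stack, `model.json`, `report.json`,
`roc.tsv`, `features.tsv`, `comparison.json` (genes+demographics vs
demographics only), and `cohort_summary.tsv`.

Reruns with the same config are byte-identical; the global seed drives
independent substreams per stage.

## Notes

- `mode="honest"` (the default) recomputes CAT ranking and voting inside
  every training fold, so effect-free data cross-validate to AUC ~ 0.5.
  `mode="full"` ranks once on all rows and is optimistically biased; it is
  provided for comparison only.
- PMM imputations are always drawn from each feature's observed values, so
  binary features stay binary without a separate model.
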