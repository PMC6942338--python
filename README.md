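# snparray

A toolkit for designing and evaluating fixed SNP genotyping arrays:

- **`snparray.simulate`** — synthetic candidate SNPs, probeset designs,
  HWE genotype truth across one or two populations (with duplicate samples
  per tree, plate structure and Dish-QC), two-channel log-normal
  intensities driven by per-SNP latent quality classes, and feature tables
  with a planted logistic success signal.
- **`snparray.design`** — candidate/probeset filtering (buildable flanks,
  A/T–C/G handling, recommendation rules with a validated-SNP exemption),
  transcript and probeset ranking, and greedy coverage-first array
  selection under a capacity budget.
- **`snparray.calling`** — a transparent stand-in genotype caller:
  contrast/size transform, 1–3 component Gaussian mixtures with
  BIC selection, per-call confidences (lower = better), cluster
  diagnostics and off-target-variant detection.
- **`snparray.qc`** — sample/plate QC, seven-category SNP classification
  (OTV, Other, CallRateBelowThreshold, NoMinorHom, MonoHighResolution,
  PolyHighResolution, Rescued), Default / Rescue (90–60 % call rate) /
  Modified protocols, and duplicate-sample genotype/allele accuracy.
- **`snparray.popgen`** — per-SNP call rate, MAF, observed/expected
  heterozygosity, PIC and HWE chi-square tests; cross-population median
  summaries and MAF histograms.
- **`snparray.success`** — BLAST-tabular feature engineering (hit bins,
  best/second PID, perfect-allele counts), likelihood-ratio chi-square,
  Welch t and Monte-Carlo Wilcoxon tests, stepwise logistic regression
  with cross-validated ROC, and a marker-detection sample-size
  calculator.
- **`snparray.tables` / `snparray.vcf` / `snparray.cli`** — strict TSV
  schemas, FASTA and VCF v4.2 export, run manifests, and a `click` CLI.

## Tests

```sh
python -m pytest -q tests/
```

The suite generates all fixtures programmatically (no data downloads) and
runs in well under a minute on one CPU.

## CLI

```sh
snparray simulate --seed 1 --n-snps 500 --out runs/sim
snparray call     --intensities runs/sim/intensities.tsv --out runs/calls
snparray qc       --calls runs/calls/calls.tsv \
                  --diagnostics runs/calls/diagnostics.tsv \
                  --samples runs/sim/samples.tsv \
                  --protocol rescue60 --out runs/qc
snparray popgen   --calls runs/calls/calls.tsv \
                  --samples runs/sim/samples.tsv --out runs/popgen
snparray predict  --features runs/sim/features.tsv --out runs/predict
snparray export   --calls runs/calls/calls.tsv \
                  --candidates runs/sim/candidates.tsv --out runs/calls.vcf
```

`snparray run-all --seed 1 --out runs/full` chains the whole pipeline;
`snparray design` filters/ranks/selects probesets from candidate tables.
Every command writes a `manifest.json` recording inputs, thresholds and
seed.

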