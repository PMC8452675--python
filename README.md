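# aimpanel

Ancestry-informative-marker (AIM) analysis pipeline for sequencing-based SNP
panels: synthetic multi-population data generation, read-count genotype QC,
marker-independence filtering, and likelihood-based biogeographic ancestry
assignment with a z-score outlier gate.

## What it does

- **`aimpanel.syndata`** — Balding–Nichols simulation of differentiated
  reference populations (per-population FST around ancestral frequencies),
  Hardy–Weinberg genotype profiles, two-way admixed profiles, and an
  amplicon-style read-count layer with configurable depth (negative
  binomial / Poisson), heterozygote allele bias, and per-read error rate.
  All randomness flows from one root seed via per-operation substreams.
- **`aimpanel.qc`** — genotype acceptance from per-nucleotide read counts:
  heterozygote balance (Hb) and noise metrics, the two acceptance rules
  (depth ≥ 45 with 0.3 ≤ Hb ≤ 3.0; depth 20–44 with zero noise and
  0.7 ≤ Hb ≤ 1.3), the >10% missingness sample filter, and panel merging
  with an explicit duplicate-marker preference rule.
- **`aimpanel.popfilters`** — exact Hardy–Weinberg tests per population
  (complete enumeration, plus a Markov-chain estimator), pairwise LD exact
  tests on complete profiles (EM haplotype frequencies + permutation null),
  Bonferroni correction, and pruning of linked pairs by marker performance
  (dropouts, noise, Hb deviation, locus balance) with amplicon length as
  the tie-breaker.
- **`aimpanel.ancestry`** — standardized profile log-likelihoods
  z = (E[ℓ] − ℓ)/SD[ℓ] against each meta-population with leave-one-out
  frequency estimation, pairwise log likelihood-ratios with standard
  errors, the Accepted / Ambiguous / Rejected classification, and
  leave-one-out cross-validation summaries.
- **`aimpanel.io` / `aimpanel.cli`** — genotyper-CSV, panel, profile and
  reference-database readers/writers, a plain-text run configuration, and a
  subcommand CLI.

## CLI

```sh
aimpanel run --outdir results --seed 1          # full synthetic pipeline
aimpanel simulate --outdir results --seed 1     # synthetic data only
aimpanel qc --input results/readcounts.csv --outdir results
aimpanel filter --outdir results --seed 1       # HWE + LD + pruning
aimpanel assign --profiles results/truth_profiles.tsv \
    --db results/reference_db.tsv --outdir results
aimpanel crossval --profiles results/truth_profiles.tsv \
    --origins results/origins.tsv --db results/reference_db.tsv --outdir results
aimpanel report --outdir results                # log-LR summary
```

`aimpanel run` executes simulate → qc → filter → assign/crossval and writes
`manifest.json` with a SHA-256 hash per artefact; identical configuration
and seed produce identical manifests. Settings can be supplied as a
key/value text file via `--config` (see `aimpanel.io.RunConfig` for the
defaults).

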