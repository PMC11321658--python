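# gutmaz

Gut-microbiota maturity and dysbiosis analysis toolkit.

`gutmaz` implements an end-to-end pipeline for quantifying gut microbiota
development and dysbiosis from OTU count tables:

- **io_core** — OTU table / taxonomy / metadata readers and writers
  (wide TSV and dense BIOM-JSON), genus collapsing, relative-abundance
  transform, pipeline configuration.
- **synthetic_cohort** — an age-structured cohort simulator with known
  ground truth: logistic-in-age genus trajectories (age-discriminatory,
  stunted-colonization, disrupted-colonization, persistent-overgrowth and
  background classes), Dirichlet-multinomial counts at variable depth,
  and a treatment → mediator → outcome structure with known standardized
  path coefficients.
- **community_metrics** — FASTQ read QC (length / mean Phred / ambiguous
  bases / homopolymer runs), rare-OTU prevalence filtering, averaged
  rarefaction (mean over resamples without replacement at 90% of the
  minimum depth, rounded), alpha diversity (Shannon, Simpson, Chao1,
  ACE, observed), Bray–Curtis + PCoA, PERMANOVA, Mantel test, and a
  pairwise Wilcoxon utility with Bonferroni–Holm correction.
- **maturity_rf** — random-forest microbiota-age regression (500 trees,
  mtry = p/3), repeated-forest age-discriminatory taxa ranking,
  age-stratified models (<3, 3–9, 10–18, >18 years), healthy reference
  construction and the microbiota-for-age Z score
  `MAZ = (microbiota age − reference median) / reference s.d.`
- **image_cnn** — the OTU-table-to-image encoder (top-abundance OTU
  selection, genus blocks ordered by abundance with >0.75-correlated
  partners adjacent, log-transformed abundances mapped to 0–255 in three
  channels), the physiological-age bin scheme (0–1 y monthly … 70–102 y
  every eight years, with underfilled-bin merging), a small numpy CNN
  classifier, and median-of-top-3 microbiota-age aggregation.
- **dysbiosis_stats** — covariate-adjusted per-feature linear models on
  arcsin-sqrt abundance with BH-FDR, Spearman co-occurrence networks
  (retain FDR < 0.05 and |rho| > 0.1), and stratified tenfold
  cross-validated random-forest classification AUC (1000 trees).
- **mediation** — logistic genus-panel mediator score, standardized
  product-of-coefficients mediation (linear-probability outcome by
  default, logistic optional) with percentile bootstrap CIs
  (5000 resamples by default).

The CNN backbone is intentionally a compact, dependency-free numpy
implementation: the encoding, age-bin classes and median-of-top-3
aggregation are the substance; full-scale deep-residual training is out
of scope at desk scale.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the end-to-end property checks (MAZ
null and directional recovery, rarefaction and PERMANOVA calibration,
encoder contract, CNN age pipeline, mediation recovery, network
thresholds, BH-FDR oracle agreement, RF classification sanity).

## CLI

```sh
gutmaz simulate --out cohort/ --seed 1 --n-samples 300
gutmaz qc reads.fastq clean.fastq
gutmaz rarefy cohort/otu_table.tsv --out rarefied.tsv
gutmaz diversity rarefied.tsv --out alpha.csv
gutmaz ordinate cohort/otu_table.tsv --out-prefix ord
gutmaz permanova cohort/otu_table.tsv cohort/metadata.csv
gutmaz maturity cohort/otu_table.tsv cohort/taxonomy.tsv cohort/metadata.csv --out-dir maz/
gutmaz encode cohort/otu_table.tsv cohort/taxonomy.tsv --out-dir images/ --side 64
gutmaz associate cohort/otu_table.tsv cohort/metadata.csv --out assoc.tsv
gutmaz network cohort/otu_table.tsv cohort/taxonomy.tsv cohort/metadata.csv --out edges.tsv
gutmaz classify cohort/otu_table.tsv cohort/metadata.csv
gutmaz mediate cohort/otu_table.tsv cohort/taxonomy.tsv cohort/metadata.csv \
    --panel OvergrowthGenus1,OvergrowthGenus2 --out mediation.json
```

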