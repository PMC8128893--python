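# crosstwas

Cross-tissue transcriptome-wide association (TWAS) pipeline operating on
GWAS summary statistics, with a closed synthetic-data generator so every
stage runs and is tested without external downloads.

Stages:

- **simulate** — LD-blocked genotypes for four disjoint cohorts,
  multi-tissue expression with shared cis-eQTL architecture, an
  expression-mediated polygenic phenotype, marginal-OLS GWAS summary
  statistics, oracle imputation weights, per-gene LD matrices, and
  negative-binomial chromatin-interaction counts.
- **weights** — multi-tissue sparse group lasso (lasso + SNP-across-tissue
  group penalty) trained by block coordinate descent, with k-fold
  cross-validated penalty selection.
- **twas** — per-tissue gene–trait statistic `w'z / sqrt(w'Dw)` after
  harmonizing weights, GWAS and LD to a common effect allele (sign flips
  on swapped alleles, strand-ambiguous and mismatching SNPs dropped).
- **combine** — generalized Berk-Jones combination of the per-tissue
  statistics, with correlation-inflated exceedance variance from the
  tissue covariance `w_t'Dw_s`, and Monte-Carlo p-values; all-tissue and
  tissue-subset (e.g. brain-only) modes.
- **consensus** — Bonferroni thresholds, dual-reference consensus calls
  with a ±1 Mb neighbor rescue, GWAS window lookups, summary counts.
- **conditional** — re-test each gene conditioning on the most significant
  variant in its imputation model, via partial-correlation algebra on
  summary statistics, recombined with GBJ and bucketed into persistence
  classes.
- **prs** — gene-based polygenic scores: per-gene training effects, the
  17-threshold profile grid, and incremental R² from the nested models
  m1–m4, alone and jointly with a variant-based GWAS PRS.
- **enrich** — chromatin-interaction counts per gene (score > 5, either
  anchor overlapping the gene body) compared between significant and
  other genes by a Wilcoxon rank-sum test (exact for small groups).

## CLI

Every stage is a subcommand of `crosstwas`; all files are plain TSV.

```sh
crosstwas simulate --seed 1 --out study/
crosstwas train-weights --expression-dir study --genotypes study/ref \
    --annotation study/annotation.tsv --out study/trained.tsv
crosstwas twas --gwas study/gwas.tsv --weights study/weights.tsv \
    --ld study/ld --out single.tsv
crosstwas combine --single-tissue single.tsv --weights study/weights.tsv \
    --gwas study/gwas.tsv --ld study/ld --b 2000 --seed 0 --out combined.tsv
crosstwas consensus --v1 combined_v1.tsv --v2 combined_v2.tsv \
    --annotation study/annotation.tsv --n-genes 22694 --n-traits 211 --out calls.tsv
crosstwas conditional --weights study/weights.tsv --gwas study/gwas.tsv \
    --ld study/ld --out conditional.tsv
crosstwas prs --train-prefix study/train --test-prefix study/test \
    --weights study/weights.tsv --tissue tissue0 --gwas study/gwas.tsv --out prs.tsv
crosstwas enrich --interactions interactions.tsv --annotation study/annotation.tsv \
    --significant sig_genes.tsv --out enrichment.tsv
```

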