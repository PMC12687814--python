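# quantqtl

Quantile-regression molecular QTL mapping for bulk and single-cell
transcriptomics (and other molecular phenotypes), with hierarchical FDR
control, quantile TWAS, and enrichment analysis.

## The problem

Conventional cis-QTL mapping regresses a molecular phenotype on genotype
dosage and tests the mean effect (here called **xQTL**). A single slope
cannot see variants that act only in the tails of the expression
distribution, change expression *variability* rather than its level, or
act only in a subgroup defined by an unmeasured context. `quantqtl`
scans the whole conditional distribution instead:

- **qQTL** — for each quantile level τ in a 19-point grid
  {0.05, …, 0.95}, the quantile-regression model
  `Q_Y(τ | G, C) = α0(τ) + C'α(τ) + G β(τ)` is tested with the
  rank-score (score-type) statistic

  `S = n^{-1/2} Σ_i G*_i φ_τ(Y_i − α̂0(τ) − C_i'α̂(τ))`,
  `φ_τ(u) = τ − 1(u < 0)`,  `σ² = τ(1−τ)‖G*‖²/n`,

  where `G*` is the dosage residualized on the covariates. The
  covariate-only null model is fitted **once per gene and level** and
  shared by every variant in the cis-window; per-level p-values are
  aggregated with the Cauchy combination (ACAT),
  `p = 1/2 − arctan(Σ w_i tan((1/2 − p_i)π))/π`.
- **vQTL** — a QUAIL-style variance test that aggregates the
  upper-minus-lower tail contrast `Σ_{τ<0.5} (S_{1−τ} − S_τ)` with its
  exact null covariance `Cov(S_a, S_b) = (min(a,b) − ab)‖G*‖²/n`.
- **iQTL** — ordinary least squares for an explicit interaction,
  `Y = β0 + βG G + βF F + βI G×F + C'βC + ε`, on the
  rank-inverse-normal-transformed phenotype, with amplifying /
  counteracting / uncertain directionality classes.
- **Hierarchical FDR** — Benjamini–Hochberg across genes on per-gene lead
  Bonferroni p-values, then a data-driven variant threshold
  `t* = max lead Bonferroni p among significant genes`.
- **qTWAS** — per gene, quantile-specific weights `ω̂(τ)` trained on a
  99-level grid, summed within quantile regions (fixed thirds or
  data-driven contiguous regions), and tested against GWAS summary
  statistics through an LD matrix:
  `Z_k = ω̂_k'z / sqrt(ω̂_k'Σω̂_k)`, Cauchy-combined across regions.
- **Enrichment** — excess-of-overlap (EOO) of variant–gene link sets with
  leave-one-chromosome-out jackknife errors, and hypergeometric gene-set
  over-representation.

A synthetic-data module generates Hardy–Weinberg genotypes, phenotypes
under null / location / scale / tail-specific / interaction models, GWAS
z-scores consistent with an LD panel, and a complete miniature study
bundle; a Monte-Carlo study compares iQTL/qQTL/xQTL detection under the
interaction model.

## Worked example

Generate a miniature study and scan it:

```sh
quantqtl synth bundle --outdir demo --seed 7 --n 400 --genes 50 --variants 5000
quantqtl run --genotypes demo/genotypes.tsv --phenotypes demo/phenotypes.bed.tsv \
    --covariates demo/covariates.tsv --tadb demo/tadb.bed \
    --gwas demo/gwas.tsv --ld demo/ld.tsv \
    --annotation demo/annotation_promoterlike.bed --outdir demo_out
```

which prints

```
5/5 stages ok; manifest at demo_out/manifest.json
```

and writes per-method pair tables (`pairs_{xqtl,qqtl,vqtl}.tsv`),
hierarchical calls (`call_*.tsv`), pair categories with Chatterjee
heterogeneity statistics (`categories.tsv`), qTWAS weights and
associations, and EOO enrichment (`eoo.tsv`). On this bundle the scan
output reproduces the planted structure: genes simulated with a pure
variance (scale) effect are called by the quantile and variance scans but
not by the linear scan, genes with a mean (location) effect are called by
all three, and e.g.

```sh
quantqtl map qqtl --genotypes demo/genotypes.tsv \
    --phenotypes demo/phenotypes.bed.tsv --covariates demo/covariates.tsv \
    --tadb demo/tadb.bed --out demo_qqtl.tsv
```

reports

```
qqtl: 17 significant genes, 17 significant pairs (t* = 0.01248...)
```

meaning 17 of the 50 genes pass the gene-level 5% FDR and, within them,
17 variant–gene pairs fall under the data-driven Bonferroni threshold
t*. One pair per gene is expected here: the bundle's variants are
simulated without linkage disequilibrium, so only each planted causal
variant associates. (Counts are deterministic for a fixed `--seed`.)

The Monte-Carlo comparison of the three scans under the interaction
model runs as

```sh
quantqtl simstudy --reps 300 --seed 1 --cells amplifying --out sim.tsv
```

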