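# pavcall

**Failed SNP-array calls as presence–absence markers for genomic
prediction.**

When an SNP array returns no genotype (`F/F`), the standard reaction is to
filter the marker out. In hybrid-breeding populations a substantial share
of those failures is caused by presence–absence variation — a deletion
spans the probe site — so the failure pattern is itself an inherited,
fully homozygous marker. `pavcall` is a pipeline for breeders and
quantitative geneticists that takes this seriously end to end:

1. **Recode** calls treating `F` as a third allele, filter on expected
   heterozygosity He = 1 − Σp² ≥ 0.095 (equivalent to MAF ≥ 0.05 for a
   biallelic locus), and split into a standard-SNP dosage matrix (0/1/2)
   and a failed-call matrix (0/2).
2. **Filter** failed-call markers for biological cause by two pipelines:
   a χ² test of independence between failure and heterotic-pool
   membership (pool-specific deletions), and a paired one-sided t-test
   comparing the failed-call profile's LD (r²) against same-chromosome
   SNPs with its own SNP profile's LD (deletions ride haplotypes; random
   dropout does not). Both use Benjamini–Hochberg at α = 0.05.
3. **Relate and predict** with VanRaden relationship matrices
   G = ZZ′ / (2Σpᵢ(1−pᵢ)) built from any marker set, and four models:
   GBLUP (y = Xβ + Za + e, a ~ N(0, G σa²)), EGBLUP (adds i ~ N(0, Gaa σaa²)
   with Gaa = G#G), Bayesian LASSO (double-exponential marker priors,
   Gibbs), and RKHS kernel averaging (Gaussian kernels, bandwidths
   {0.1, 0.5, 2.5}).
4. **Evaluate** by repeated fivefold cross-validation with masked
   phenotypes, scored as the Pearson r between observed and predicted
   values, with folds shared across models so comparisons are paired.
5. **Verify the null**: inject purely random failures into simulated
   traits (effects N(0,1), Ve = Vg/H² − Vg) and show the filters retain
   essentially nothing and failed-call prediction accuracy is ~0.

A synthetic two-pool doubled-haploid population generator (Balding–
Nichols pool divergence, blockwise haplotype LD, pool- and haplotype-
linked deletions, technical dropout, additive traits at target
heritability) makes every stage testable without any external data.
See `docs/methods.md` for the full model description.

## Worked example

Generate a population with two planted deletions carrying trait effects,
run the whole pipeline from one config:

```yaml
# config.yaml
seed: 3
cv_repeats: 2
synth:
  n_per_pool: 100
  n_chrom: 3
  markers_per_chrom: 80
  epsilon: 0.02          # random technical dropout
  h2: 0.6
  n_trait_qtl: 30
  deletions:
    - {chrom: chr1, start_marker: 20, end_marker: 23,
       freq_pool_a: 0.4, freq_pool_b: 0.05, effect: 1.0}
    - {chrom: chr2, start_marker: 40, end_marker: 43,
       freq_pool_a: 0.05, freq_pool_b: 0.45, effect: -1.0}
models: [gblup]
```

```sh
$ pavcall synth      --config config.yaml --outdir run
synth: 200 samples x 240 markers
$ pavcall preprocess --config config.yaml --outdir run
preprocess: 240 -> He 225 -> SNP 208 / failed 9
$ pavcall cluster    --config config.yaml --outdir run
cluster: 73 in A, 127 in B
$ pavcall filter-ps  --config config.yaml --outdir run
filter-ps: kept 8 of 9
$ pavcall filter-ld  --config config.yaml --outdir run
filter-ld: kept 2 of 9
$ pavcall cv         --config config.yaml --outdir run
cv: gblup/snp median r = 0.627
cv: gblup/failed median r = 0.151
```

Reading the output: of 240 raw markers, 225 pass the third-allele
diversity screen; the SNP branch keeps 208 after imputation and MAF
filtering, while only 9 markers fail often enough (≥5% of lines) to enter
the failed-call branch — the planted deletion spans plus a little dropout.
The pool-specificity filter keeps 8 of 9 (the planted deletions have
strongly pool-divergent carrier frequencies), the stricter LD filter keeps
2. Fivefold CV then puts SNP-based GBLUP at median r = 0.627 and
failed-call-only GBLUP at 0.151 — nine presence–absence markers already
predict, because two of them tag the causal deletions. Each stage writes
its artifacts (TSV matrices, filter reports, GRMs, CV tables) and a JSON
manifest of seeds and checksums into `run/`; rerunning a stage with the
same config reproduces identical files.

The same machinery is available as a library
(`pavcall.preprocess`, `pavcall.filters`, `pavcall.grm`,
`pavcall.models`, `pavcall.crossval`, `pavcall.synth`,
`pavcall.simstudy`) for anything the CLI doesn't expose, e.g. EGBLUP or
RKHS fits, relationship-coefficient correlations between marker sets, or
custom simulation designs.

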