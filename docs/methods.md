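# Methods

## The problem

SNP arrays return, for every (sample, probe) pair, one of `AA`, `AB`, `BB`
— or nothing. Standard pipelines discard markers with many failed calls.
In hybrid-breeding material, however, a large share of failures is not
technical noise but presence–absence variation: a genomic deletion spans
the probe site in some lines and the assay has nothing to hybridize to.
The failure pattern is then itself an inherited, homozygous marker.
`pavcall` implements the full analysis built on that idea: recode failures
as a 0/2 marker matrix, separate biologically caused from random failures
with two statistical filters, estimate genomic relationships and predict
quantitative traits from failed calls alone or combined with SNPs, and
verify by simulation that *random* failures carry no signal.

## Recoding and filtering (the two-branch pipeline)

The failed state `F` is treated as a third allele next to `A` and `B`.
With allele frequencies p = (pA, pB, pF), a marker is retained when its
expected heterozygosity

    He = 1 − Σ p_i²  ≥  0.095

This threshold is exactly the He of a biallelic locus at minor allele
frequency 0.05 (2·0.05·0.95 = 0.095), so the screen reduces to the usual
MAF ≥ 0.05 rule when nothing fails; with failures present it admits a
marker whose *failure* is the polymorphism. The retained matrix is copied:

* **SNP branch** — `FF` is re-declared missing, imputed (below), coded
  0/1/2 by B-allele count, then MAF ≥ 0.05-filtered;
* **failed-call branch** — recoded 0 (any successful call) / 2 (`FF`),
  then filtered on F/F genotype frequency in [0.05, 0.95] (the two-sided
  minor-allele bound under the homozygous coding).

Imputation is a stand-in, not a contribution: the default draws each
missing genotype from the marker's observed genotype frequencies under a
seed (preserving allele frequencies in expectation), `mode` imputation and
externally imputed input are alternatives. Downstream models see only
dosages, so phasing quality is irrelevant here.

## Separating biological from random failures

**Pool specificity.** Hybrid breeding maintains diverged heterotic pools;
deletions drift to pool-specific frequencies, technical dropout cannot.
Pool labels come from k-means (k = 2, k-means++, 25 restarts, seeded) on
standard-SNP dosages. Per failed-call marker, a χ² test of independence on
the 2×2 table pool × {called, failed} (df 1, no continuity correction — a
`low_expected_count` column flags tables with expected cells < 5 instead
of switching tests). Benjamini–Hochberg across all candidates; **keep**
when adjusted p < 0.05 (rejecting independence is evidence of biology).

**Linkage disequilibrium.** A deletion travels with its haplotype, so its
failure pattern should be in LD with flanking SNPs; random dropout is in
LD with nothing. Per marker, r² (squared dosage correlation — exact
composite LD for fully homozygous lines) of (a) the failed-call profile
and (b) the marker's own SNP profile against the identical set of other
same-chromosome SNPs; a *paired*, one-sided t-test of (a) − (b) (pairing
over the common SNP set maximizes power); BH across markers; **keep** when
the failed profile is *not* significantly lower (adjusted p ≥ 0.05).
Keep-on-non-rejection is anticonservative by construction — low power
means more markers kept — and two failure modes are documented:

* if no SNP on the chromosome is in LD with anything, both profiles are
  ≈ 0 and every marker is kept (the test cannot discriminate);
* if a deletion removes essentially all carriers of one haplotype class,
  the imputed SNP copy can go monomorphic, be MAF-filtered, and leave the
  failed-call marker without a counterpart — such markers are flagged
  untestable and conservatively not kept.

## Relationship and prediction

All marker sets (SNP, failed, the two filtered failed sets, and
column-concatenated combinations with one joint scaling constant) enter
the VanRaden genomic relationship matrix

    G = Z Z′ / (2 Σ p_i (1 − p_i)),   Z = M − 2p,

with p the B-allele (or failed-allele) frequency. The epistatic
relationship is the Hadamard square Gaa = G # G (PSD by the Schur product
theorem). Four predictors:

* **GBLUP** — y = Xβ + a + e, a ~ N(0, G σa²). REML by eigendecomposition
  of the X-projected G and a 1-D profile search over λ = σa²/σe² (grid on
  log λ ∈ [−9, 9]·ln10, Brent refinement, xatol 1e−10).
* **EGBLUP** — adds i ~ N(0, Gaa σaa²). Multi-component REML: L-BFGS-B on
  log variances with the analytic restricted-likelihood gradient
  (∂ℓ/∂σk² = −½[tr(P Kk) − y′P Kk P y]), gtol 1e−6, max 200 iterations;
  non-convergence is flagged and the best iterate returned.
* **Bayesian LASSO** — y = Xβ + Ma + e with double-exponential priors on
  marker effects via the scale-mixture-of-normals Gibbs sampler: flat β;
  a_j | τ_j², σe² ~ N(0, σe² τ_j²); 1/τ_j² inverse-Gaussian; σe²
  scaled-inverse-χ² (df 5, scale keyed to an assumed marker-explained
  variance share R² = 0.5); λ² ~ Gamma(1.1, rate set so the prior mode is
  λ̂² = 2·MSx·(1−R²)/R², MSx the summed marker variances). Defaults 6,000
  iterations, 1,000 burn-in, thin 5; deterministic under a fixed seed;
  these constants are documented choices, not claimed identical to any
  other implementation's defaults.
* **RKHS kernel averaging** — K_l = exp(−h_l · D̃) for h ∈ {0.1, 0.5, 2.5},
  with D̃ the squared-Euclidean genotype distance divided by its mean
  off-diagonal value, so the bandwidth grid spans global-to-local
  smoothing regardless of marker count; one REML variance component per
  kernel (same engine as EGBLUP).

Fixed effects are an intercept plus reference-coded factor columns (first
level dropped — an intercept plus one indicator per family is rank
deficient; predictions are invariant to the reference choice).

Held-out samples are predicted by the conditional expectation
û_test = K[test,train] K[train,train]⁻¹ û_train per component (eigh-based
pseudo-inverse when the training block is singular, e.g. low-rank
failed-call GRMs), plus X_test β̂.

A note on heritability readout: the per-individual genetic variance is
σa²·G_ii, so the reported ĥ² weights each component by the mean diagonal
of its kernel. This matters here because the VanRaden denominator assumes
Hardy–Weinberg heterozygosity, which fully homozygous DH lines lack —
their G has mean diagonal ≈ 2, and the naive ratio σa²/(σa²+σe²) would be
badly biased.

## Cross-validation

Fivefold CV, 30 repeats by default: per repeat a seeded random partition
into folds of size ⌊n/5⌋ or ⌈n/5⌉; train on the complement, predict the
fold with phenotypes masked, score by Pearson r. Fold assignments depend
only on (base seed + repeat), so models and marker sets compared at the
same base seed see identical folds (paired comparisons). Folds with
constant predictions yield a missing r (recorded and counted), not a zero
— zeros would bias summaries. The headline summary is the median over all
fold × repeat values.

## The synthetic population generator

The generator provides data with exactly the structure the analysis
assumes, so every stage is testable without external downloads:

* **Two pools, Balding–Nichols divergence.** Pool frequency ~
  Beta(p(1−Fst)/Fst, (1−p)(1−Fst)/Fst) per pool around an ancestral p ~
  U(0.1, 0.9); Fst default 0.2.
* **Blockwise frequencies + first-order chain (LD).** A new frequency
  block starts with probability 1−ρ at each marker; all markers of a block
  share one ancestral frequency and one divergence draw per pool. Within a
  chromosome, each haplotype allele follows a first-order Markov chain
  whose transition probabilities preserve every marker's marginal
  frequency exactly while giving adjacent-marker correlation ρ (within a
  block this is literally "copy the previous allele with probability ρ,
  else draw fresh"). Both pieces are needed: binary variables with
  mismatched marginals cannot exceed a Fréchet correlation bound (≈ r²
  0.35 however strong the copying), and a chain without marginal
  preservation smears each marker's frequency into a moving average of its
  neighbours, which erodes the planted pool divergence. Defaults ρ = 0.9,
  10 chromosomes × 200 markers, 250 lines/pool.
* **DH lines.** One haplotype per chromosome, doubled: calls are AA/BB
  only, never AB — matching doubled-haploid material and the paper-style
  homozygous failure coding.
* **Deletions.** An event spans consecutive markers with per-pool carrier
  frequencies and an optional trait effect. Carriers are enrolled from the
  allele-1 class of the first span marker first (random order within
  class), so the deletion rides the local haplotype and is detectable by
  the LD filter; carriers are FF across the span.
* **Technical dropout.** Each non-FF cell independently goes FF with
  probability ε — the null process for FDR tests.
* **Traits.** g = Σ dosage(QTL)·effect + Σ carrier·deletion-effect, with
  QTL sampled outside deletion spans, effects N(0,1), and residual
  variance Ve = Vg/h² − Vg so realized heritability matches the target.
  FF cells contribute zero dosage: the allele is physically absent, which
  is precisely why deletion effects are invisible to the SNP branch and
  recoverable from the failed-call branch.

What the generator does **not** emulate: recombination maps and coalescent
genealogy (LD is first-order only, so long-range LD is absent), copy-number
variation other than clean deletions, genotyping intensity and allele-
specific dropout, half-sib family structure (a NAM-style layered mode is
out of scope), and selection. Passing tests therefore demonstrate the
statistical machinery under the stated model, not performance on any real
array dataset.

## The null-simulation study

Per replicate: simulate a trait from the clean genotypes (QTL + N(0,1)
effects, Ve as above), inject exactly N uniform-random FF entries (default
rate 2% of cells), re-run the entire recoding pipeline and both filters,
and cross-validate GBLUP on the SNP set and on the failed-call set. At
realistic injection rates the ≥0.05 frequency filter alone empties the
failed-call candidate set (a 2% uniform rate almost never yields 5%
failures at one marker), so the prediction arm uses the *complete*
failed-call set — every marker with at least one failure — which is also
what makes the null result meaningful: even given all that noise, the
failed-call GRM is uncorrelated with the SNP GRM and CV accuracy sits at
zero, while SNP accuracy tracks the simulated heritability.

## Problem sizes and numerical choices

Default desk scale: 500 lines × 2,000 markers for the survivor-count
analysis (20 replicates), 300 × 1,000 with 30 replicates for the
null-accuracy analysis, 12 replicates per heritability for REML recovery —
chosen so the whole suite and the acceptance script each run in well under
a minute while keeping Monte-Carlo error far inside the assertion bands
(e.g. the null-accuracy mean is estimated to ±0.02 against a ±0.1 band).
The paper-scale settings (10,000 QTL, 100 simulations, full arrays) are
reachable through the same configs.

Other numerics: GRMs are bent (diagonal shift) only when the smallest
eigenvalue is below −1e−8·max; BH is applied once per pipeline per
dataset, never per chromosome; zero-variance LD pairs are dropped pairwise
from both profiles; mode imputation breaks ties AA < AB < BB; all
stochastic steps take explicit seeds and the CLI derives per-stage seeds
from one master seed via a CRC of the stage name, so stages are
independently reproducible.

## Known limitations

* The LD filter's keep-on-non-rejection logic rewards low power; on data
  with weak chromosome-wide LD it keeps nearly everything.
* Heterozygous-with-failure states (one allele reads, one deleted) are not
  representable: failure is all-or-nothing, as in the homozygous coding.
* The Bayesian LASSO reports posterior means only; no convergence
  diagnostics beyond a crude ESS of the residual-variance chain.
* Combined marker sets enter a single G (one Z, one scaling constant);
  a two-kernel treatment of SNP + failed sets would estimate separate
  variance shares but is not what the single-matrix combination defines.
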