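# Methods

## The statistical procedure

`sysgene` estimates the joint contribution of a panel of candidate-gene
polymorphisms (and their functional subsystems) to a quantitative phenotype
under a polygenic small-effects assumption: no single locus is expected to
explain much variance, so loci are screened liberally and their cumulative
effect is assessed at the system level, with the multiple-testing burden paid
once, at the system level, by permutation.

**Coding.** After QC, autosomal SNPs are coded 1 (major homozygote) /
2 (heterozygote) / 3 (minor homozygote); the linear coding is justified when
screening shows no heterozygote-advantage pattern (heterozygotes
significantly beyond both homozygotes in the same direction), which the
screening ANOVA makes visible before the coding choice matters.  Loci whose
heterozygote/minor-homozygote classes were collapsed in QC become 1/2.
X-linked loci are coded 1 (major-allele homozygote or male major-allele
hemizygote) vs 2 (others), pooling the sexes — male hemizygotes are treated
as the homozygote of their single allele.  Multi-allelic VNTRs are
dummy-coded genotype *groups*; the default rule for the DRD4 48-bp repeat is
`4R/4R` vs any-2R-carrier (`2R+`, including a hypothetical 2R/7R genotype)
vs all others, with "others" as reference, yielding two yoked dummy columns.
Minor allele means lower *sample* allele frequency; ties break
lexicographically.

**QC order** is missingness → call quality → monomorphic/rare-genotype
handling → HWE → LD pruning.  HWE (χ² with expected counts n·p², 2npq, n·q²
from sample allele frequencies, df = 1, females only for X loci, uncollapsed
genotype counts) is report-only: deviating loci are retained, since in a
homogeneous volunteer sample deviation more often reflects sampling than
genotyping error.  LD r² is the squared Pearson correlation of additive
genotype codes (composite LD — raw phase is unobserved, so this approximates
haplotype-based r²); "adjacent" is interpreted as *within the same gene*,
and within each gene the first locus in panel order is kept from every
linked group.  VNTRs are never LD-pruned.

**Screening** is a one-way ANOVA of the phenotype across genotype classes,
pairwise-complete, at uncorrected α = 0.05 — deliberately liberal, because
type-I control is delegated to the permutation step.  Post hoc pairwise
comparisons use Fisher LSD (uncorrected t with the pooled ANOVA error
variance), consistent with the uncorrected screening philosophy.  An
equivalent ANOVA from per-group (mean, SD, N) summaries
(SSB = Σnᵢ(mᵢ−m̄)², SSW = Σ(nᵢ−1)sᵢ²) reproduces the raw-data F exactly and
lets published association tables be re-verified without raw data.

**Regression.** Model 1 enters all screened loci simultaneously (listwise
complete rows).  Model 2 offers every pairwise interaction of the Model 1
loci — products of de-meaned codes, de-meaned over the Model 1 analysis rows
and re-centered (the raw product's mean equals the factors' sample
covariance; re-centering zeroes it and changes nothing but the intercept) —
to a pure forward stepwise search: at each step the candidate with the
smallest partial-F p-value enters while that p < α_enter (default 0.05, same
as screening; the entry criterion is partial-F rather than AIC), ties break
in candidate order, no backward elimination, rank-deficient candidates are
skipped.  Both dummy columns of a VNTR pair enter as one yoked block (one
partial-F test with df = block width).  Environment covariates (parental
warmth; stressful-life-event counts for three life periods) are offered raw
(unstandardized) by the same stepwise rule on top of a genetic model.
Subsystem fits restrict Model 1/2 to each subsystem's selected loci;
subsystems with none get R² = 0 by convention, flagged `empty`.

**Model comparison.** Gaussian −2LL = n·ln 2π + n·ln(RSS/n) + n;
AIC = −2LL + 2p and BIC = −2LL + p·ln n with p the predictor count
*excluding* intercept and error variance (this convention is what makes the
information criteria consistent with the likelihood-ratio χ² on Δ(−2LL)
between nested fits on identical rows).  Environment-augmented models are
compared against the genetic model they extend.

**Permutation.** Each of B (default 1000) iterations shuffles the phenotype
across subjects, keeps genotypes and environment intact, and re-runs
screening, Model 1, stepwise Model 2 and all subsystem fits from scratch;
the selected-locus count varies freely and zero-selection shuffles
contribute R² = 0.  One shuffle per iteration feeds every scope, so scopes
share Monte Carlo noise.  Empirical p = (#{null ≥ observed} + 1)/(B + 1),
never exactly zero.  Permutation b uses a Philox generator keyed
(seed, 5, b), so results are bit-reproducible and independent of evaluation
order.  Both R² and adjusted R² nulls are recorded.

## The synthetic cohort generator

The generator's defaults are the study conditions the package is tested
under: 480 subjects (male fraction 208/480), 98 loci in four dopamine
subsystems (25 synthesis, 24 degradation/transport including nine X-linked
MAOA/MAOB loci and the MAOA VNTR, 29 receptor including the DRD4 VNTR,
20 modulation), ~0.2% missing calls, ~0.5% of calls below the 0.25 quality
cutoff.

* **LD** is induced by finite haplotype pools per block rather than a
  coalescent model: loci of a block share the subject's two haplotype draws
  from a pool of H haplotypes (H = 2 by default, giving r² = 1), with minor
  alleles nested on the leading haplotypes.  Pool allele frequencies are
  quantized to multiples of 1/H (H = 2 forces block-locus MAF to 0.5).  Six
  within-gene blocks plant exactly 11 redundant loci, so default QC retains
  87 of 98.  This is sufficient to exercise pruning; it does not model decay
  of LD with distance.
* **Phenotype**: intercept + Σβ·code + Σγ·(de-meaned code products) +
  Σδ·environment + N(0, σ²).  The default truth puts additive effects on ten
  unblocked autosomal SNPs (signs and relative sizes following the emulated
  study's coefficient pattern) scaled analytically — coded-SNP variance is
  2q(1−q) under HWE — to a 12% main-effect variance share, three
  cross-subsystem interactions worth 3%, and 1.03 phenotype points per
  recent stressful life event; intercept and σ place the phenotype at
  mean ≈ 122.3, SD ≈ 15.7.  With effects this small, screening recovers
  roughly half the causal loci per cohort — which is exactly the regime the
  permutation machinery exists for.
* **Items**: a one-factor model, item_j = √r·z + √(1−r)·e_j, with the
  inter-item correlation r solved from α = k·r/(1+(k−1)·r) (default k = 27,
  α = 0.817), discretized to the 1–7 scale.  Rounding attenuates realized
  alpha slightly (~0.01 at the defaults).
* **Environment**: Gaussian copula with the target latent correlation matrix
  (warmth vs events −0.11/−0.10/−0.18; events 0.34/0.24/0.41), Poisson
  marginals for event counts (means 2.7/4.5/2.5) and a rounded-normal
  marginal for parental warmth (53.0, SD 7.5).  Matching Poisson marginals
  to the target *means* leaves realized count SDs at √mean, below the
  emulated study's reported SDs (its counts are overdispersed); discrete
  marginals also attenuate realized Pearson correlations by ~0.02 at the
  defaults.
* All randomness flows through counter-based Philox generators keyed on an
  explicit seed; identical seed and configuration give a bit-identical
  cohort.

What passing tests on these cohorts do *not* show about real data: no
population structure or relatedness, no genotyping-error model beyond
uniform missingness and the quality layer, LD only within planted blocks,
no item reversals or response styles, equidispersed event counts.

## Numerical conventions and edge cases

* Sample SDs and variances use the n−1 denominator throughout.
* Screening selection is strict p < α on the unrounded p-value (internally
  F > F⁻¹(1−α) with cached critical values).
* ANOVA uses pairwise-complete subjects per locus; regression uses listwise
  complete rows over its predictor set; interaction terms are built on the
  Model 1 rows, so Models 1 and 2 share rows.
* Loci whose observed classes collapse to one group are reported unselected
  with F = NaN rather than erroring the panel.
* Rare-genotype collapsing merges only classes that are present (a locus
  with zero minor homozygotes needs no merge and keeps 1/2/3 coding with an
  empty top class, i.e. observed codes {1, 2}).
* Rank-deficient designs raise, naming the collinear columns; stepwise
  silently skips rank-deficient candidates instead.
* `compare_models` of a model with itself returns Δ = 0, df = 0, p = 1.
* Tiny negative Δ(−2LL) from floating-point noise in nested fits is clipped
  to 0.

## Design choices that were genuinely open

* Whether the emulated study's HWE test used collapsed or original genotype
  counts is unstated; original counts are used.
* The composite (genotype-code) LD r² is used in place of an EM/haplotype
  estimator; at these sample sizes and for pruning at a 0.8 threshold the
  distinction is immaterial.
* The stepwise entry criterion (partial-F p at α = 0.05) and the treatment
  of environment models as nested extensions of the *genetic* models are
  choices consistent with the reported degrees of freedom of the emulated
  analysis; both are exposed as parameters.
* The acceptance/test problem sizes (e.g. type-I calibration with 200
  replicate cohorts of 20 loci, n = 200, B = 199) are scaled-down study
  conditions chosen so the exact binomial check retains power at desk scale.

## Known limitations

* Pure forward selection: an interaction is reachable only if both parent
  loci screened in, and entered terms are never removed — both mirror the
  emulated procedure and both are structural biases of it.
* Composite LD, no phasing, no imputation, no relatedness screening.
* Gaussian OLS likelihoods; no robust/sandwich errors, no penalized
  alternatives (a LASSO-style path would change the selection-optimism
  story and is out of scope).
* Gene–environment interaction terms are not modeled.
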