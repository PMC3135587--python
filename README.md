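# sysgene

**System-level candidate-gene association analysis with honest post-selection
inference.**

Single polymorphisms typically explain well under 1% of the variance of a
behavioral trait, far below twin-study heritability estimates. `sysgene`
implements the alternative: quantify the *joint* contribution of all typed
polymorphisms of one neuronal gene system (e.g. the dopamine pathway and its
synthesis, degradation/transport, receptor and modulation subsystems) to a
quantitative phenotype, through a multi-step pipeline —

1. **Genotype QC** — subject missingness filter, per-call quality (GenCall)
   cutoff, rare-genotype collapsing, Hardy–Weinberg χ² (df = 1; females only
   on X), within-gene LD pruning at r² > 0.8;
2. **Screening** — per-locus one-way ANOVA of the phenotype across genotype
   classes, nominating loci at uncorrected p < 0.05, with Fisher-LSD post hoc
   comparisons;
3. **Regression** — *Model 1*: all screened loci entered simultaneously
   (autosomal SNPs coded 1/2/3 by genotype, X loci 1/2 pooling the sexes,
   VNTRs dummy-coded); *Model 2*: plus pairwise SNP×SNP interaction terms
   (products of de-meaned codes) chosen by forward stepwise partial-F tests;
   subsystem-restricted fits; environment covariates offered by the same
   stepwise rule; nested models compared by Δ(−2LL) against χ², with
   AIC = −2LL + 2p and BIC = −2LL + p·ln n;
4. **Permutation** — the phenotype is shuffled and the *entire* pipeline
   (screening included) is re-run per shuffle, so the null distribution of
   model R² carries the full selection optimism of step 2–3; empirical
   p = (#{null ≥ observed} + 1)/(B + 1).

Because screening and fitting use the same data, a parametric p-value on the
screened model is anti-conservative; the whole-pipeline permutation null is
the package's answer to that.

A first-class **synthetic cohort generator** reproduces the statistical
structure the analysis assumes — ~480 subjects × 98 loci in four subsystems,
within-gene LD blocks from finite haplotype pools, X-linked hemizygous male
calls, a multi-allelic 48-bp VNTR with the `4R/4R` / `2R+` / others grouping,
Likert item responses with target Cronbach's alpha, and count-valued
stressful-life-event covariates from a Gaussian copula with Poisson
marginals — so the whole pipeline is testable end to end without external
data.

## Worked example

```python
import sysgene as sg

bundle = sg.simulate_cohort(seed=3)              # 480 subjects x 98 loci
g_qc, report = sg.run_qc(bundle.genotypes)       # -> 87 loci, 11 LD-pruned

results = sg.screen_panel(g_qc, bundle.phenotype)
selected = [r.locus for r in results if r.selected]

design = sg.code_loci(g_qc)
m1 = sg.build_model1(design, selected, bundle.phenotype)
m2 = sg.build_model2(design, selected, bundle.phenotype, model1=m1)
comp = sg.compare_models(m1, m2)

perm = sg.run_null_pipeline(g_qc, bundle.phenotype, B=999, seed=3)
```

With this seed the run prints (via the obvious format strings):

```
loci retained: 87 | LD-pruned: 11 | calls masked: 242
screened loci (p<0.05): 8 ['rsTH01', 'rsDDC06', 'rsDRD202', 'rsDRD306',
                           'rsNLN01', 'rsNTS01', 'rsNTSR101', 'rsNTSR201']
Model 1: R2=0.114 adjR2=0.098 F(8,448)=7.19
Model 2: R2=0.133 adjR2=0.114 entered=['rsNLN01×rsNTS01', 'rsDDC06×rsDRD306']
LRT: delta(-2LL)=10.0 df=2 p=6.6e-03
AIC 3804 -> 3798   BIC 3837 -> 3839
environment entered: ['events_college'] dR2=0.015 p=5.5e-03
permutation p, Model 1: {'whole': 0.004, 'synthesis': 0.177,
  'degradation_transport': 1.0, 'receptor': 0.241, 'modulation': 0.001}
```

Reading: of 98 simulated loci, 87 survive QC; eight screen in at p < 0.05;
their joint main effects explain 11.4% of phenotype variance (Model 1), two
stepwise interaction terms raise that to 13.3% and are jointly supported by
the likelihood-ratio test (p ≈ 0.007); recent stressful life events add
~1.5% on top of the genetic model.  The permutation p of 0.004 says that
only ~4 of 1000 shuffled phenotypes — each given the *same* freedom to
select its own best loci — reached the observed Model 1 R², and localizes
the signal in the modulation subsystem, where the generative truth indeed
concentrates it.

The same pipeline runs from the shell:

```bash
sysgene run-all --out run1 --seed 3 -B 999           # simulate -> ... -> report
sysgene qc --genotypes G.tsv --loci L.tsv --out run2 # or start from your data
```

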