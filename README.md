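# pdprs — pleiotropy-decomposed polygenic risk scores

A genome-wide polygenic risk score (PRS) for a complex disease aggregates
risk alleles acting through very different biological routes — lipid
metabolism, blood pressure, inflammation, and so on. Two people in the top
5% of the same PRS can carry entirely different risk profiles. `pdprs`
implements a region-based decomposition that makes this heterogeneity
visible and testable: it partitions a PRS into mutually exclusive,
biologically labelled component scores, stratifies high-genetic-risk
individuals into pleiotropy subgroups, and quantifies the genetic and
phenotypic differences between them, including gene–environment
interaction on both multiplicative and additive scales.

It is aimed at statistical geneticists and genetic epidemiologists working
with GWAS summary statistics, PRS weight files and individual-level
genotype/phenotype data.

## Method

Let the genome be divided into nearly LD-independent blocks
(b = 1..B). For the target disease and each of K candidate traits with
standardized marginal effects β̂, the block-level **local genetic
covariance** between target t and trait a is estimated by the moment
cross-product

    ĉ_b(t, a) = Σ_{j ∈ b} β̂_tj β̂_aj ,

which is unbiased for Σ β_tj β_aj when the GWAS cohorts do not overlap.
Its null distribution treats effects as random: under genetic
independence, Var(ĉ) = Σ_j (v_t + σ_tj²)(v_a + σ_aj²), with v the
noise-corrected per-SNP genetic variance of the block — so the Wald test
is calibrated even in polygenic blocks where the realized covariance of
independent effects is not exactly zero.

Each block is then assigned to the trait with a significant local
correlation (two-sided p < 0.05) and the **largest |ĉ|**; blocks with no
significant trait form the non-specific OTHERS set. Traits map to
pleiotropy clusters (a domain-knowledge configuration), SNPs inherit
their block's cluster, and the cluster's **PD-PRS** is the usual weighted
allele-dosage sum restricted to its SNPs. Because the clusters partition
the SNPs, the PD-PRSs sum exactly to the overall PRS.

Among individuals above the population 95th percentile of the overall
PRS, the **pleiotropy subgroup** for cluster c is those also above the
95th percentile of PD-PRS_c. For a trait L, subgroup heterogeneity is the
relative change (L_S − L_R)/SD: subgroup mean minus remaining-high-risk
mean over the trait SD among all high-risk individuals. PRS × trait
interactions are tested by residualizing the trait on covariates and the
PD-PRSs, applying the rank-based inverse normal transform, and comparing
nested (Cox or linear) models with and without the interaction term via a
1-df likelihood-ratio test, with Benjamini–Hochberg FDR across pairs.
Additive-scale interaction among high-risk individuals is summarized by
RERI = (ARR_subgroup − ARR_remaining)/R00 with a Delta-method test.

The package also ships (a) a generative simulator — block-structured
effect sizes with designated causal and locally correlated regions, GWAS
noise at a chosen sample size, copula-LD genotypes and interaction-bearing
phenotypes — and (b) the SVD decomposition baseline (LD pruning, SVD of
the trait × effect matrix, component and residual PRSs) the region-based
method is compared against.

## Worked example

One simulated replicate at reduced scale — 47 blocks × 100 SNPs, four
traits, GWAS noise at n = 50,000, 4,000 individuals:

```python
from pdprs.pipeline import run_replicate

rep = run_replicate(seed=7, n_individuals=4000)
print(rep.relative_changes.round(2))
print(rep.interaction.round(4))
```

```
subgroup  OTHERS  trait2  trait3  trait4
trait
trait2     -0.02    0.55    0.00   -0.03
trait3      0.53   -0.36    0.71   -0.09
trait4     -0.06   -0.32   -0.24    0.49

 trait  coefficient     lrt   p  converged
trait2       0.2244 18.0652 0.0   True
trait3       0.2466 22.4458 0.0   True
trait4       0.2748 25.2772 0.0   True
```

The diagonal of the first table is the focal relative change: members of
the trait-2 subgroup average 0.55 high-risk SDs more of trait 2 than the
remaining high-risk individuals, while off-diagonal (non-focal) entries
are near zero or negative — the decomposition separates genetically
distinct high-risk subgroups with visibly different phenotypes. The
second table shows the recovered PD-PRS × trait interaction coefficients
(generative value 0.3 per moderator SD; GWAS estimation noise attenuates
the estimate) with all likelihood-ratio tests highly significant.

## Command line

`pdprs` exposes the stages as subcommands: `simulate`, `localcov`,
`decompose`, `score`, `subgroups`, `interact`, `reri`, `svd-baseline`,
plus `run` (sequence the pipeline from one YAML config, with pre-flight
path checks and a hashed output manifest) and `reproduce-simulation`
(the full simulation experiment from one root seed):

```bash
pdprs reproduce-simulation --seed 1 --n 10000 --seeds 10 --out report.json
```

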