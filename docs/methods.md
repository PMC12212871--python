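# Methods

This note records the models, estimators, parameter choices and numerical
conventions behind `pdprs`, and what the synthetic-data experiments do and
do not establish.

## Local genetic covariance and block assignment

Marginal effect estimates on the standardized-genotype scale satisfy
β̂ = β + ε with Var(ε_j) ≈ 1/n per SNP. For a nearly LD-independent block
the cross-product ĉ = Σ_j β̂_aj β̂_bj is unbiased for the local genetic
covariance Σ_j β_aj β_bj provided the two GWAS share no samples (sample
overlap induces correlated noise and a bias term; no overlap correction is
implemented, and overlapping cohorts are outside the estimator's
assumptions).

**Null variance.** The Wald test uses a random-effects null: if the two
traits' per-SNP effects are independent draws with per-SNP variances v_a,
v_b, then Var(ĉ) = Σ_j (v_a + σ_aj²)(v_b + σ_bj²), where v is estimated
by the noise-corrected mean square (1/m)Σ(β̂² − σ²), floored at zero, and
the total is floored at Σ σ_a²σ_b² (the pure-noise minimum). The
fixed-effect alternative — conditioning on the realized β and propagating
only estimation noise — is anticonservative for testing *genetic
independence* in polygenic blocks, because independent effect vectors
still have a realized covariance of order sqrt(m)·v: measured type-I
error 0.12 at nominal 0.05 versus 0.03–0.05 for the random-effects form.
The p-value is two-sided.

**LD-aware path.** When a block LD matrix R is supplied, effects are
projected onto the leading eigenvectors of R covering 90% of its variance
(ridge-regularized if numerically singular), scaled by 1/sqrt(eigenvalue)
so projected noise is homoskedastic, and the same moment formulas apply in
the decorrelated coordinates. The simulation pipeline generates effects
directly on the standardized joint scale with i.i.d. GWAS noise, so it
uses the identity-LD path; the projection path serves real marginal
summary statistics. Blocks with fewer than two usable SNPs are flagged and
fall to the non-specific cluster.

**Assignment rule.** Per block, among traits with p < α (α = 0.05,
configurable) the largest |ĉ| wins; "not significant" means not(p < α).
Exact |ĉ| ties (measure zero on real data, constructible in tests) break
deterministically by the configured trait order. Estimation failures are
treated as non-significant. The partition of SNPs is exhaustive and
mutually exclusive by construction, which is what makes the component
scores sum to the overall PRS (relative tolerance 1e-8 is asserted in
tests; the identity is exact up to floating-point summation order).

**Global correlation.** For trait selection, rg = Σ_b ĉ_b / sqrt(H_a H_b)
with H_t = Σ β̂² − Σ σ² a noise-corrected heritability proxy; the SE is a
leave-one-block-out jackknife (≥ 10 blocks required), selection is
Benjamini–Hochberg at FDR 0.05, and the clustering sensitivity analysis is
average-linkage agglomeration on distance 1 − |rg|.

## Subgroups and heterogeneity metrics

Quantiles use linear interpolation between order statistics and
membership is strict ">" of the threshold; high risk is the top q = 0.05
of the overall PRS and subgroup membership additionally requires the top
q of the cluster's PD-PRS over the whole population. Membership may
overlap and may be empty — both carry information.

Relative change is (L_S − L_R)/SD (means for quantitative traits,
prevalences for binary ones), with SD always computed among *all*
high-risk individuals — for binary traits, the SD of the 0/1 indicator.
The statistic is invariant to affine rescaling of a quantitative trait
and undefined (flagged) when the high-risk SD is zero.

Contribution fractions face a sign problem: PD-PRSs can be negative, so
raw ratios are ill-defined. The default convention shifts each component
by its minimum over the high-risk population before normalizing per
individual, preserving stacked-bar semantics (fractions in [0,1], summing
to 1); an individual at the minimum of every component receives uniform
fractions by symmetry. The alternative |PD|/Σ|PD| convention is available
via `method="abs"`; both are reported because the normalization behind
published contribution percentages is a convention, not an estimate.

## Interaction analysis

Traits are residualized (linear for continuous, logistic for binary —
response residuals of a binary trait are not the trait, and results carry
that caveat) on the configured covariate set, which includes the PD-PRSs;
residuals are transformed by the rank-based inverse normal transform with
Blom offset, Φ⁻¹((r − 3/8)/(n + 1/4)), average ranks for ties. Since the
transform depends on ranks only, any monotone rescaling of the trait
yields identical downstream tests (a property test asserts this). The
interaction is tested by a 1-df LRT between nested models with and
without PRS × moderator — Cox proportional hazards for (time, event)
outcomes, OLS for continuous outcomes (the simulated target trait is
continuous, so the simulation experiment uses the linear likelihood).
Non-convergence flags the pair instead of raising. FDR control is
Benjamini–Hochberg step-up at 0.05.

For dichotomized exposures among high-risk individuals, the four cells of
(subgroup, remaining) × (exposed, unexposed) give hazard ratios against
the remaining-unexposed reference, absolute risks (case proportions), ARR
= AR_exposed − AR_unexposed per stratum, and RERI = (ARR_subgroup −
ARR_remaining)/R00. The Delta-method variance propagates the four cells'
independent binomial variances A(1−A)/n through the gradient of
f = (A_se − A_su − A_re + A_ru)/A_ru; a bootstrap cross-check in the test
suite agrees within 15%. Cells without observations, or R00 = 0, flag the
result as undefined.

## The generative simulator

The simulator emulates a chromosome-scale study: 47 nearly independent
blocks (default 100 SNPs each), four traits with Trait 1 the target.
Region roles are drawn disjointly: Trait 1 is causal in 10 blocks, 3 of
which are shared with each component trait (9 in total, disjoint across
pairs); each component trait adds 7 unique causal blocks; the correlated
regions for a pair are its 3 shared causal blocks, 2 of the component
trait's unique causal blocks, and 5 blocks causal for no trait — 10 per
pair, also disjoint across pairs. Within a block, per-SNP effects across
traits are multivariate normal with variance h²(trait, block)/m and
cross-trait correlation `local_rg` inside the pair's correlated regions.

Key defaults, and why:

* `total_h2 = 0.5` per trait, causal regions carrying 10× the per-region
  background heritability — "causal regions have higher heritability"
  made concrete; background effects are nonzero everywhere (an
  infinitesimal component) so local correlation is defined in non-causal
  correlated regions.
* `local_rg = 0.9`. The focal relative change of a component trait in its
  own subgroup is approximately 1.46 · 0.48 · rg ≈ 0.70 · rg under this
  design (0.48·rg is the implied trait/PD-PRS correlation, 1.46 the
  expected standardized score gap between subgroup and remaining members
  of the top-5% set), so reported focal changes in the 60–77% range imply
  rg near 0.9–1; 0.6 would cap them near 42%.
* `n_gwas = 50,000`: i.i.d. N(0, 1/n) estimation noise per SNP,
  independent across traits (no cohort overlap).
* Genotypes: MAF ~ U(0.05, 0.5), Hardy–Weinberg dosages from two latent
  AR(1) Gaussian haplotypes per individual (`ld_decay = 0.9`), blocks
  independent. Dichotomization attenuates the latent correlation, more at
  low MAF, giving adjacent-dosage correlations around 0.3–0.8.
* Phenotypes: Trait_k = 2·G_k + E_k + 0.3·G_k·E_k with G_k the
  standardized true genetic score and E_k ~ N(0,1). Trait 1 keeps the
  same structure and adds Σ_k [1·Trait_k + 0.3·z(Trait_k)·S_k], where
  S_k is the standardized true Trait-1 score restricted to pair k's
  correlated regions. The moderator enters *standardized* so that the
  generative coefficient 0.3 lives on the per-SD scale that the
  rank-INT interaction analysis estimates; with a raw moderator
  (SD ≈ 2.26) the analysis would estimate ≈ 0.68 and no analysis of this
  form could recover the nominal value. S_k is truth-based (computable
  before any estimation), not a post-hoc estimated score.
* All randomness flows from one root seed through named substreams
  (betas, noise, genotypes, phenotypes), so stages are independently
  reproducible and bit-identical under a repeated seed.

**What the simulator does not emulate:** real LD (haplotype structure,
long-range LD, MAF–LD coupling), marginal-vs-joint effect convolution
through LD, binary disease outcomes with censoring and competing risks,
covariate structure (age, sex, ancestry), assortative mating or
stratification, and cohort overlap between GWAS. Passing recovery tests
therefore demonstrates internal consistency of the decomposition and
interaction machinery under the declared generative model, not
performance on cohort data.

## SVD baseline

The comparison method LD-prunes (greedy scan, keep unless r² > 0.2 with a
kept SNP inside a 250-SNP window; pruning runs within blocks since blocks
are independent), takes the SVD of the trait × pruned-SNP effect matrix,
and retains the smallest k components reaching 80% cumulative squared
singular value. Component PRSs are built by hard assignment: each pruned
SNP belongs to the singular vector carrying its largest absolute loading,
a component's weights are the target weights restricted to its SNPs, and
SNPs whose best component is not retained form the residual — components
plus residual exactly reconstruct the pruned target PRS. An alternative
construction (projection of the target weights onto each singular vector)
is available; it also reconstructs exactly, but each component score is
then a dense trait-mixture score that behaves like a full trait-specific
GWAS PRS and no longer represents a decomposition into SNP subsets. A
singular vector's sign carries no information, so before thresholding a
component subgroup, the component score is oriented to associate
positively with its focal trait.

## The reproduction experiment

`reproduce-simulation` (and `scripts/acceptance.py`) runs the whole chain
at desk scale: 20 independently seeded replicates of 10,000 individuals
(47 blocks × 100 SNPs) for the subgroup and SVD comparisons, and 100
replicates of 5,000 individuals for the interaction sweep — sizes chosen
so the averages are stable (per-seed SD of a focal relative change is
roughly 10 percentage points) and the weakest true interactions remain
detectable at α = 0.05. Expected behavior, all recomputed at run time:
focal relative changes large and positive, non-focal means negative,
block-assignment recovery essentially perfect for designated regions, the
SVD baseline materially weaker than the block decomposition, and mean
interaction coefficients below the generative 0.3 by the product of GWAS
noise attenuation (corr(S, PD-PRS) ≈ 0.93 at n_gwas = 50,000) and the
residualization's removal of the moderator's PRS-aligned part (≈ 0.95) —
an attenuation inherent to the analysis, not an implementation artifact.

## Known limitations

* The local estimator ignores sample overlap and uses a simplified
  eigen-projection instead of a full regional likelihood.
* Per-SNP effects are Gaussian; no sparsity, MAF-dependent architecture
  or annotation structure.
* Logistic-residual interaction results are approximations (the caveat is
  surfaced in the API).
* The RERI Delta variance treats the four cells as independent binomials,
  ignoring covariate adjustment of the cell risks.
* Contribution fractions depend on the declared normalization convention;
  both implemented conventions should be reported together.
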