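"""Generative simulator for GWAS effect sizes, genotypes and phenotypes.

The simulated genome is a set of nearly independent LD blocks (47 by
default, mirroring a chromosome-22-scale partition). Four traits are
generated; Trait 1 is the target whose PRS is later decomposed:

* each trait is causal in ``n_causal_regions_per_trait`` blocks (10),
  where per-region heritability is ``causal_h2_ratio`` times the
  background level, with per-trait total heritability ``total_h2``;
* for every component trait k in {2, 3, 4}, three of Trait 1's causal
  regions are shared with trait k (disjoint across the three pairs), and
  the correlated-region set for the pair is those 3 shared causal blocks
  plus 2 of trait k's unique causal blocks plus 5 blocks causal for no
  trait — 10 correlated regions per pair, with cross-trait effect
  correlation ``local_rg`` inside them and 0 everywhere else;
* GWAS sampling noise with per-SNP variance 1/n_gwas (n_gwas = 50,000) is
  added independently per trait (no sample overlap);
* genotypes are Hardy-Weinberg dosages with MAF ~ U(maf_range) and
  within-block LD from a Gaussian-copula latent with AR(1) parameter
  ``ld_decay`` (blocks are independent);
* phenotypes: for k in {2,3,4}, Trait_k = 2*G_k + E_k + 0.3*G_k*E_k with
  G_k the standardized true genetic score and E_k ~ N(0,1); Trait 1 keeps
  its own genetic/non-genetic/interaction structure and additionally
  receives each component trait and its interaction with the standardized
  true region-restricted score S_k, with weights 1 and 0.3.

The interaction moderator in Trait 1 is the *standardized* component
trait so that the generative coefficient 0.3 is expressed per moderator
SD — the scale on which the downstream rank-INT interaction analysis
estimates it. S_k is the truth-based score over the pair's correlated
regions (generation never depends on estimation).

All randomness flows from one root seed through named substreams, so the
beta, noise, genotype and phenotype stages are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from pdprs.io import GenotypeMatrix

TARGET = 0  # index of the target trait (Trait 1)

_SUBSTREAMS = ("betas", "noise", "genotypes", "phenotypes")


class DesignError(ValueError):
    """Simulation design violates its composition invariants."""


@dataclass
class SimDesign:
    """Fully materialized study design for one simulation replicate."""

    n_blocks: int = 47
    n_traits: int = 4
    n_causal_regions_per_trait: int = 10
    n_shared_causal: int = 3
    n_unique_causal_correlated: int = 2
    n_noncausal_correlated: int = 5
    correlated_regions_per_pair: int = 10
    snps_per_block: int = 100
    total_h2: float = 0.5
    causal_h2_ratio: float = 10.0
    local_rg: float = 0.9
    n_gwas: int = 50_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay: float = 0.9
    pheno_weights: tuple[float, float, float] = (2.0, 1.0, 0.3)
    target_weights: tuple[float, float] = (1.0, 0.3)
    seed: int = 0

    # materialized by make_design
    causal_regions: dict[int, np.ndarray] = field(default_factory=dict)
    shared_regions: dict[int, np.ndarray] = field(default_factory=dict)
    correlated_regions: dict[int, np.ndarray] = field(default_factory=dict)
    mafs: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_snps(self) -> int:
        return self.n_blocks * self.snps_per_block

    @property
    def component_traits(self) -> range:
        return range(1, self.n_traits)

    def block_slice(self, block: int) -> slice:
        m = self.snps_per_block
        return slice(block * m, (block + 1) * m)

    def block_h2(self, trait: int, block: int) -> float:
        """Per-region heritability: causal regions carry ratio x background."""
        n_c = self.n_causal_regions_per_trait
        base = self.total_h2 / (n_c * self.causal_h2_ratio + (self.n_blocks - n_c))
        return base * self.causal_h2_ratio if block in self.causal_regions[trait] else base

    def truth_table(self) -> pd.DataFrame:
        """Block-level ground-truth labels for recovery testing."""
        rows = []
        for b in range(self.n_blocks):
            causal_for = [t + 1 for t in range(self.n_traits)
                          if b in self.causal_regions[t]]
            correlated_with = [k + 1 for k in self.component_traits
                               if b in self.correlated_regions[k]]
            rows.append({
                "block_id": b,
                "causal_for": ",".join(map(str, causal_for)),
                "correlated_with": correlated_with[0] if correlated_with else 0,
            })
        return pd.DataFrame(rows)


@dataclass
class SimOutput:
    """Everything one replicate produces, including the generative truth."""

    design: SimDesign
    true_betas: np.ndarray      # traits x SNPs
    noisy_betas: np.ndarray     # the simulated GWAS
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame    # trait1..trait4 (+ diagnostics)
    realized_local_cov: pd.DataFrame
    _x_std: np.ndarray | None = None

    @property
    def snp_ids(self) -> list[str]:
        return self.genotypes.snps

    def standardized_dosages(self) -> np.ndarray:
        """Column-standardized dosage matrix, computed once and cached."""
        if self._x_std is None:
            self._x_std = standardize_dosages(self.genotypes.dosages)
        return self._x_std


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_SUBSTREAMS, children)}


def make_design(seed: int = 0, **overrides) -> SimDesign:
    """Materialize a design: region roles, pair structure and SNP MAFs.

    Deterministic given the seed. Raises :class:`DesignError` when the
    requested composition is infeasible (correlated-region composition not
    summing to the pair total, or too few blocks for disjoint roles).
    """
    design = replace(SimDesign(), seed=seed, **overrides)
    d = design
    n_pairs = d.n_traits - 1
    if (d.n_shared_causal + d.n_unique_causal_correlated + d.n_noncausal_correlated
            != d.correlated_regions_per_pair):
        raise DesignError("correlated-region composition must sum to "
                          f"{d.correlated_regions_per_pair} (got "
                          f"{d.n_shared_causal}+{d.n_unique_causal_correlated}"
                          f"+{d.n_noncausal_correlated})")
    if d.n_shared_causal * n_pairs > d.n_causal_regions_per_trait:
        raise DesignError(
            f"{d.n_shared_causal} shared regions per pair x {n_pairs} pairs exceed the "
            f"{d.n_causal_regions_per_trait} causal regions of the target trait")
    n_unique_k = d.n_causal_regions_per_trait - d.n_shared_causal
    if d.n_unique_causal_correlated > n_unique_k:
        raise DesignError("not enough unique causal regions per component trait")
    need = (d.n_causal_regions_per_trait + n_pairs * n_unique_k
            + n_pairs * d.n_noncausal_correlated)
    if need > d.n_blocks:
        raise DesignError(f"design needs {need} blocks but only {d.n_blocks} available")
    if abs(d.local_rg) > 1:
        raise DesignError("|local_rg| must be <= 1")

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    pool = list(rng.permutation(d.n_blocks))

    def take(k: int) -> np.ndarray:
        out = np.array([pool.pop() for _ in range(k)], dtype=int)
        return out

    target_causal = take(d.n_causal_regions_per_trait)
    shared = {k: target_causal[(k - 1) * d.n_shared_causal:k * d.n_shared_causal]
              for k in range(1, d.n_traits)}
    causal = {TARGET: target_causal}
    correlated = {}
    for k in range(1, d.n_traits):
        unique_k = take(n_unique_k)
        causal[k] = np.concatenate([shared[k], unique_k])
        corr_unique = rng.choice(unique_k, size=d.n_unique_causal_correlated,
                                 replace=False)
        noncausal = take(d.n_noncausal_correlated)
        correlated[k] = np.concatenate([shared[k], corr_unique, noncausal])

    design.causal_regions = causal
    design.shared_regions = shared
    design.correlated_regions = correlated
    design.mafs = rng.uniform(*d.maf_range, size=d.n_snps)
    return design


def simulate_true_betas(design: SimDesign,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw per-SNP true effects (traits x SNPs), block by block.

    Within a block, SNP effects across traits are multivariate normal with
    per-trait variance h2(trait, block)/m and cross-trait correlation
    ``local_rg`` between the target and a component trait inside that
    pair's correlated regions (0 elsewhere; component traits are mutually
    uncorrelated by design).
    """
    if not design.causal_regions:
        raise DesignError("design not materialized; call make_design")
    if abs(design.local_rg) > 1:
        raise DesignError("|local_rg| must be <= 1")
    rng = rng if rng is not None else _rngs(design.seed)["betas"]
    T, m = design.n_traits, design.snps_per_block
    betas = np.empty((T, design.n_snps))
    for b in range(design.n_blocks):
        sd = np.array([np.sqrt(design.block_h2(t, b) / m) for t in range(T)])
        corr = np.eye(T)
        for k in design.component_traits:
            if b in design.correlated_regions[k]:
                corr[TARGET, k] = corr[k, TARGET] = design.local_rg
        cov = corr * np.outer(sd, sd)
        betas[:, design.block_slice(b)] = rng.multivariate_normal(
            np.zeros(T), cov, size=m, method="eigh").T
    return betas


def add_gwas_noise(true_betas: np.ndarray, n_gwas: int,
                   rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Add GWAS estimation noise: beta-hat = beta + N(0, 1/n_gwas) i.i.d.

    Noise is independent across traits (non-overlapping GWAS cohorts).
    """
    if n_gwas <= 0:
        raise ValueError("n_gwas must be positive")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    return true_betas + rng.normal(0.0, np.sqrt(1.0 / n_gwas), size=true_betas.shape)


def simulate_genotypes(n_individuals: int, design: SimDesign,
                       rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Hardy-Weinberg dosages with within-block AR(1) copula LD.

    Two latent haplotype vectors per individual follow an AR(1) Gaussian
    within each block; an allele is carried where the latent falls below
    the MAF quantile, so marginal allele frequencies equal the drawn MAFs
    and blocks are independent.
    """
    from scipy.stats import norm

    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    if not design.causal_regions:
        raise DesignError("design not materialized; call make_design")
    rng = rng if rng is not None else _rngs(design.seed)["genotypes"]
    m, rho = design.snps_per_block, design.ld_decay
    dosages = np.empty((n_individuals, design.n_snps), dtype=np.int8)
    thresholds = norm.ppf(design.mafs)
    scale = np.sqrt(1.0 - rho ** 2)
    for b in range(design.n_blocks):
        eps = rng.standard_normal((2 * n_individuals, m))
        z = np.empty_like(eps)
        z[:, 0] = eps[:, 0]
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + scale * eps[:, j]
        alleles = (z < thresholds[design.block_slice(b)]).astype(np.int8)
        dosages[:, design.block_slice(b)] = alleles[::2] + alleles[1::2]
    iids = [f"I{i:06d}" for i in range(n_individuals)]
    snps = [f"snp{j:05d}" for j in range(design.n_snps)]
    return GenotypeMatrix(iids=iids, snps=snps, dosages=dosages,
                          a1=["A"] * design.n_snps, a2=["G"] * design.n_snps)


def standardize_dosages(dosages: np.ndarray) -> np.ndarray:
    """Column-standardize a dosage matrix (constant columns stay zero)."""
    x = np.asarray(dosages, dtype=np.float64)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


def simulate_phenotypes(genotypes: GenotypeMatrix, true_betas: np.ndarray,
                        design: SimDesign,
                        rng: np.random.Generator | None = None,
                        x_std: np.ndarray | None = None) -> pd.DataFrame:
    """Generate the four phenotypes from genotypes and true effects.

    Returns a table indexed by IID with columns trait1..trait4 plus the
    standardized truth-restricted scores S_k (``score_trait{k}``) kept for
    diagnostics. ``x_std`` lets callers reuse an already-standardized
    dosage matrix.
    """
    rng = rng if rng is not None else _rngs(design.seed)["phenotypes"]
    x = x_std if x_std is not None else standardize_dosages(genotypes.dosages)
    if x.shape[1] != true_betas.shape[1]:
        raise ValueError("genotype columns do not match the beta manifest")
    w_g, w_e, w_i = design.pheno_weights
    w_t, w_ti = design.target_weights
    n = x.shape[0]

    g = np.stack([_zscore(x @ true_betas[t]) for t in range(design.n_traits)])
    e = rng.standard_normal((design.n_traits, n))
    traits = w_g * g + w_e * e + w_i * g * e

    out = {}
    target = traits[TARGET].copy()
    for k in design.component_traits:
        cols = np.concatenate([np.arange(design.n_snps)[design.block_slice(b)]
                               for b in design.correlated_regions[k]])
        s_k = _zscore(x[:, cols] @ true_betas[TARGET, cols])
        target += w_t * traits[k] + w_ti * _zscore(traits[k]) * s_k
        out[f"trait{k + 1}"] = traits[k]
        out[f"score_trait{k + 1}"] = s_k
    out["trait1"] = target
    cols = [f"trait{t + 1}" for t in range(design.n_traits)]
    cols += [f"score_trait{k + 1}" for k in design.component_traits]
    return pd.DataFrame(out, index=pd.Index(genotypes.iids, name="IID"))[cols]


def realized_local_covariance(design: SimDesign, true_betas: np.ndarray) -> pd.DataFrame:
    """Per-block realized cross-trait covariance of the true effects."""
    rows = []
    for b in range(design.n_blocks):
        sl = design.block_slice(b)
        for k in design.component_traits:
            rows.append({
                "block_id": b,
                "trait": f"trait{k + 1}",
                "true_cov": float(true_betas[TARGET, sl] @ true_betas[k, sl]),
                "designated": bool(b in design.correlated_regions[k]),
            })
    return pd.DataFrame(rows)


def simulate_all(design: SimDesign, n_individuals: int) -> SimOutput:
    """Run the full generative model for one replicate."""
    rngs = _rngs(design.seed)
    true_betas = simulate_true_betas(design, rngs["betas"])
    noisy = add_gwas_noise(true_betas, design.n_gwas, rngs["noise"])
    geno = simulate_genotypes(n_individuals, design, rngs["genotypes"])
    x_std = standardize_dosages(geno.dosages)
    pheno = simulate_phenotypes(geno, true_betas, design, rngs["phenotypes"],
                                x_std=x_std)
    return SimOutput(design=design, true_betas=true_betas, noisy_betas=noisy,
                     genotypes=geno, phenotypes=pheno,
                     realized_local_cov=realized_local_covariance(design, true_betas),
                     _x_std=x_std)
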