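"""Block assignment, SNP partitioning and PD-PRS computation.

Each LD block is assigned to the candidate trait with a significant local
covariance (two-sided p < alpha) and the largest |covariance|; blocks with
no significant trait — or where estimation failed — fall into the
non-specific OTHERS cluster. Assigned traits are mapped to pleiotropy
clusters, SNPs are partitioned by their block's cluster, and each
cluster's PD-PRS is the weighted allele-dosage sum over its SNPs. By
construction the cluster scores sum to the overall PRS for every
individual.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from pdprs.io import OTHERS, ClusterConfig, GenotypeMatrix, LdBlock, ValidationError


def assign_block(estimates: pd.DataFrame, alpha: float = 0.05,
                 trait_order: list[str] | None = None) -> str | None:
    """Pick the winning trait for one block, or None (non-specific).

    ``estimates`` has one row per candidate trait with columns trait, cov,
    p (and optionally ok). Among traits with p < alpha the one with the
    largest |cov| wins; exact ties break deterministically by
    ``trait_order`` (input order by default). Rows flagged not-ok are
    ignored.
    """
    if estimates.empty:
        raise ValueError("assign_block needs at least one candidate estimate")
    est = estimates.copy()
    if "ok" in est.columns:
        est = est[est["ok"].astype(bool)]
    est = est[np.isfinite(est["p"]) & (est["p"] < alpha)]
    if est.empty:
        return None
    order = trait_order if trait_order is not None else list(estimates["trait"])
    rank = {t: i for i, t in enumerate(order)}
    est = est.assign(_abs=est["cov"].abs(), _rank=est["trait"].map(rank))
    est = est.sort_values(["_abs", "_rank"], ascending=[False, True], kind="stable")
    return str(est["trait"].iloc[0])


def assign_blocks(local_cov: pd.DataFrame, alpha: float = 0.05,
                  trait_order: list[str] | None = None) -> pd.DataFrame:
    """Assign every block; returns block_id, trait (None = non-specific),
    winning |cov| and p."""
    rows = []
    for block_id, grp in local_cov.groupby("block_id", sort=True):
        trait = assign_block(grp, alpha=alpha, trait_order=trait_order)
        if trait is None:
            rows.append({"block_id": block_id, "trait": None,
                         "cov": np.nan, "p": np.nan})
        else:
            win = grp[grp["trait"] == trait].iloc[0]
            rows.append({"block_id": block_id, "trait": trait,
                         "cov": float(win["cov"]), "p": float(win["p"])})
    return pd.DataFrame(rows)


def label_partition(assignments: pd.DataFrame, cluster_config: ClusterConfig,
                    blocks: list[LdBlock]) -> dict[str, list[str]]:
    """Partition all block SNPs into cluster-labelled, disjoint subsets.

    Blocks assigned to a trait contribute their SNPs to that trait's
    pleiotropy cluster; unassigned blocks go to OTHERS. The result is
    exhaustive over every SNP carried by the blocks.
    """
    by_id = {b.block_id: b for b in blocks}
    assigned_trait = dict(zip(assignments["block_id"], assignments["trait"]))
    partition: dict[str, list[str]] = {c: [] for c in cluster_config.clusters}
    for block_id, block in by_id.items():
        trait = assigned_trait.get(block_id)
        if trait is None or (isinstance(trait, float) and np.isnan(trait)):
            cluster = OTHERS
        else:
            cluster = cluster_config.cluster_of(str(trait))
        partition[cluster].extend(block.snp_ids)
    return partition


def compute_pd_prs(genotypes: GenotypeMatrix | np.ndarray,
                   weights: pd.DataFrame | np.ndarray,
                   partition: dict[str, list[str]],
                   snp_ids: list[str] | None = None,
                   iids: list[str] | None = None,
                   cluster_order: list[str] | None = None) -> pd.DataFrame:
    """Weighted-dosage scores per cluster plus the overall PRS.

    ``weights`` is either a weight table (snp/weight columns, assumed
    harmonized to the genotype orientation) or a vector aligned with the
    genotype SNPs. Missing dosages are mean-imputed per SNP. Returns a
    table indexed by IID with column OVERALL followed by one column per
    cluster; the cluster columns sum to OVERALL for every individual.
    """
    if isinstance(genotypes, GenotypeMatrix):
        x = np.asarray(genotypes.dosages, dtype=float)
        snps = genotypes.snps
        ids = genotypes.iids
    else:
        x = np.asarray(genotypes, dtype=float)
        if snp_ids is None:
            raise ValueError("snp_ids required with a raw dosage matrix")
        snps = list(snp_ids)
        ids = iids if iids is not None else [f"I{i:06d}" for i in range(x.shape[0])]
    pos = {s: j for j, s in enumerate(snps)}

    if isinstance(weights, pd.DataFrame):
        missing = [s for s in weights["snp"] if s not in pos]
        if missing:
            raise ValidationError(
                f"{len(missing)} weighted SNP(s) absent from genotypes: {missing[:10]}")
        w = np.zeros(x.shape[1])
        w[[pos[s] for s in weights["snp"]]] = weights["weight"].to_numpy(dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape[0] != x.shape[1]:
            raise ValidationError(
                f"weight vector length {w.shape[0]} != {x.shape[1]} genotype SNPs")

    if np.isnan(x).any():
        col_mean = np.nanmean(x, axis=0)
        idx = np.where(np.isnan(x))
        x = x.copy()
        x[idx] = np.take(col_mean, idx[1])

    clusters = cluster_order if cluster_order is not None else list(partition)
    seen: set[str] = set()
    for c in clusters:
        dup = seen.intersection(partition.get(c, []))
        if dup:
            raise ValidationError(f"partition is not disjoint; shared SNPs: "
                                  f"{sorted(dup)[:5]}")
        seen.update(partition.get(c, []))

    out = pd.DataFrame(index=pd.Index(ids, name="IID"))
    out["OVERALL"] = x @ w
    for c in clusters:
        mask = np.zeros(x.shape[1])
        mask[[pos[s] for s in partition.get(c, []) if s in pos]] = 1.0
        out[c] = x @ (w * mask)
    return out
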