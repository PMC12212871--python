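"""SVD decomposition baseline for PRS components.

The comparison method: LD-prune to approximately independent SNPs, take
the singular value decomposition of the trait x SNP effect-size matrix,
retain the smallest number of components whose squared singular values
cover a cumulative variance threshold (80% by default), and build one
component PRS per retained right-singular direction plus a residual PRS.

Component weights are the projections of the target trait's pruned PRS
weights onto each retained right-singular vector, so that component
scores plus the residual score exactly reconstruct the pruned-SNP target
PRS — a testable conservation property mirroring the block-based
decomposition's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ComponentDecomposition:
    pruned_snps: list[str] | np.ndarray
    singular_values: np.ndarray
    components: np.ndarray          # k x pruned-SNPs right-singular vectors
    cumulative_variance: np.ndarray
    n_components: int
    component_weights: np.ndarray   # k x pruned-SNPs PRS weight vectors
    residual_weights: np.ndarray    # pruned-SNPs
    target_weights: np.ndarray


def ld_prune(dosages: np.ndarray, r2_threshold: float = 0.2,
             window: int = 250) -> np.ndarray:
    """Greedy LD pruning: scan SNPs in order, keep one unless its r² with
    an already-kept SNP inside the window exceeds the threshold.

    Returns the kept column indices. Deterministic given input order;
    monomorphic SNPs are skipped (their r² is undefined).
    """
    x = np.asarray(dosages, dtype=float)
    if x.size == 0:
        return np.array([], dtype=int)
    sd = x.std(axis=0)
    mu = x.mean(axis=0)
    n = x.shape[0]
    kept: list[int] = []
    z = np.where(sd > 0, 1.0, np.nan)  # marker for monomorphic columns
    zx = (x - mu) / np.where(sd > 0, sd, 1.0)
    for j in range(x.shape[1]):
        if sd[j] == 0:
            continue
        near = [i for i in kept if j - i <= window]
        if near:
            r = zx[:, near].T @ zx[:, j] / n
            if np.max(r ** 2) > r2_threshold:
                continue
        kept.append(j)
    return np.array(kept, dtype=int)


def svd_decompose(beta_matrix: np.ndarray, target_weights: np.ndarray,
                  var_threshold: float = 0.8,
                  snp_ids: list[str] | None = None,
                  construction: str = "assign") -> ComponentDecomposition:
    """Decompose the trait x SNP effect matrix into component PRS weights.

    Retains the smallest k with cumulative squared-singular-value fraction
    >= ``var_threshold``. Two component-PRS constructions are offered:

    * ``"assign"`` (default): each pruned SNP goes to the component
      carrying its largest absolute loading across all singular vectors;
      SNPs whose best component is not retained form the residual.
      Component m's weights are the target weights restricted to its SNPs,
      so components + residual partition (and exactly reconstruct) the
      pruned target PRS.
    * ``"projection"``: component m's weight vector is the projection of
      the target weights onto the m-th right-singular vector; the residual
      is what remains. Also reconstructs exactly, but each component score
      is then a full trait-mixture score rather than a SNP subset.
    """
    b = np.asarray(beta_matrix, dtype=float)
    w = np.asarray(target_weights, dtype=float)
    if b.ndim != 2 or min(b.shape) < 2:
        raise ValueError("beta matrix needs at least 2 traits and 2 SNPs")
    if not np.any(b):
        raise ValueError("degenerate all-zero beta matrix")
    if w.shape[0] != b.shape[1]:
        raise ValueError("target weights must align with the beta matrix SNPs")
    if construction not in ("assign", "projection"):
        raise ValueError(f"unknown construction {construction!r}")
    _, s, vt = np.linalg.svd(b, full_matrices=False)
    frac = np.cumsum(s ** 2) / np.sum(s ** 2)
    k = int(np.searchsorted(frac, var_threshold - 1e-12) + 1)
    comps = vt[:k]
    if construction == "projection":
        comp_w = (comps @ w)[:, None] * comps
        resid_w = w - comp_w.sum(axis=0)
    else:
        best = np.argmax(np.abs(vt), axis=0)
        comp_w = np.stack([np.where(best == m, w, 0.0) for m in range(k)])
        resid_w = np.where(best >= k, w, 0.0)
    ids = snp_ids if snp_ids is not None else np.arange(b.shape[1])
    return ComponentDecomposition(
        pruned_snps=ids, singular_values=s, components=comps,
        cumulative_variance=frac, n_components=k,
        component_weights=comp_w, residual_weights=resid_w, target_weights=w)


def component_scores(dosages_pruned: np.ndarray, decomp: ComponentDecomposition,
                     iids: list[str] | None = None) -> pd.DataFrame:
    """Per-individual component, residual and pruned-total PRS values.

    COMP1..COMPk + RESIDUAL sum to PRUNED_TOTAL by construction.
    """
    x = np.asarray(dosages_pruned, dtype=float)
    out = pd.DataFrame(index=pd.Index(
        iids if iids is not None else range(x.shape[0]), name="IID"))
    for m in range(decomp.n_components):
        out[f"COMP{m + 1}"] = x @ decomp.component_weights[m]
    out["RESIDUAL"] = x @ decomp.residual_weights
    out["PRUNED_TOTAL"] = x @ decomp.target_weights
    return out


def associate_components(scores: pd.DataFrame, traits: pd.DataFrame,
                         alpha: float = 0.05) -> tuple[dict[str, str], pd.DataFrame]:
    """Regress each trait on each (standardized) component score.

    Returns (component -> best-associated trait by |standardized
    coefficient|, full association table with a Bonferroni flag at
    alpha/(n_components x n_traits)).
    """
    comp_cols = [c for c in scores.columns if c.startswith("COMP")]
    bonf = alpha / (len(comp_cols) * traits.shape[1])
    rows = []
    for comp in comp_cols:
        z = (scores[comp] - scores[comp].mean()) / scores[comp].std()
        for trait in traits.columns:
            y = traits[trait].to_numpy(dtype=float)
            slope, _, r, p, _ = stats.linregress(z.to_numpy(), y)
            rows.append({"component": comp, "trait": trait,
                         "coefficient": float(slope / y.std()),
                         "p": float(p), "significant": bool(p < bonf)})
    table = pd.DataFrame(rows)
    best = {}
    for comp, grp in table.groupby("component"):
        best[comp] = str(grp.loc[grp["coefficient"].abs().idxmax(), "trait"])
    return best, table
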