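"""High-risk stratification, pleiotropy subgroups and heterogeneity metrics.

High risk = overall PRS above the population (1-q)-quantile (q = 0.05 by
default). A cluster's pleiotropy subgroup is the high-risk individuals who
are also above the population (1-q)-quantile of that cluster's PD-PRS;
membership may overlap across clusters and some high-risk individuals
belong to none. Per cluster, the "remaining" set is high-risk individuals
outside that subgroup.

Relative change of a trait between a subgroup and its remaining set is
(L_S − L_R)/SD — mean (or, for a disease, prevalence) difference over the
trait's SD among all high-risk individuals.

Contribution fractions: PD-PRS components can be negative, so each
component is shifted by its minimum over the high-risk population before
normalizing per individual (keeps the stacked-bar reading: fractions sum
to 1). The alternative |PD|/Σ|PD| convention is available via ``method``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from pdprs.io import OTHERS  # noqa: F401  (re-exported for pipeline convenience)


@dataclass
class SubgroupAssignment:
    high_risk: pd.Series            # bool per individual (whole population)
    membership: pd.DataFrame        # bool, rows = individuals, cols = clusters
    overall_threshold: float
    cluster_thresholds: pd.Series
    q: float

    @property
    def clusters(self) -> list[str]:
        return list(self.membership.columns)

    def subgroup(self, cluster: str) -> pd.Index:
        m = self.membership[cluster] & self.high_risk
        return m.index[m]

    def remaining(self, cluster: str) -> pd.Index:
        m = self.high_risk & ~self.membership[cluster]
        return m.index[m]


def assign_subgroups(scores: pd.DataFrame, q: float = 0.05) -> SubgroupAssignment:
    """Flag high-risk individuals and their per-cluster subgroup membership.

    ``scores`` holds OVERALL plus one column per cluster over the full
    population. Quantiles use linear interpolation; membership is strict
    ">" of the threshold.
    """
    if not (0 < q < 0.5):
        raise ValueError("q must lie in (0, 0.5)")
    clusters = [c for c in scores.columns if c != "OVERALL"]
    thr_overall = float(np.quantile(scores["OVERALL"], 1 - q))
    high = scores["OVERALL"] > thr_overall
    thr = pd.Series({c: float(np.quantile(scores[c], 1 - q)) for c in clusters})
    member = pd.DataFrame(
        {c: high & (scores[c] > thr[c]) for c in clusters}, index=scores.index)
    return SubgroupAssignment(high_risk=high, membership=member,
                              overall_threshold=thr_overall,
                              cluster_thresholds=thr, q=q)


def subgroup_patterns(assignment: SubgroupAssignment) -> pd.Series:
    """Count high-risk individuals by their exact set of subgroups.

    Patterns are comma-joined cluster names ("" for no subgroup); counts
    sum to the number of high-risk individuals. Sorted by count descending.
    """
    mem = assignment.membership.loc[assignment.high_risk]
    pats = mem.apply(lambda row: ",".join(mem.columns[row.to_numpy(bool)]), axis=1)
    counts = pats.value_counts()
    counts.index.name = "pattern"
    return counts


def contribution_fractions(scores: pd.DataFrame, assignment: SubgroupAssignment,
                           method: str = "min_shift"
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-individual cluster contribution fractions among high-risk people.

    Returns (fractions, summary): fractions is rows = high-risk
    individuals x cluster columns summing to 1; summary holds mean and sd
    of each cluster's fraction inside every subgroup and its remaining
    set. A cluster whose score is constant across the high-risk population
    contributes fraction 0 (with a warning).
    """
    clusters = assignment.clusters
    hr = scores.loc[assignment.high_risk, clusters]
    if method == "min_shift":
        shifted = hr - hr.min(axis=0)
    elif method == "abs":
        shifted = hr.abs()
    else:
        raise ValueError(f"unknown contribution method {method!r}")
    degenerate = shifted.columns[(shifted.max(axis=0) == 0)]
    if len(degenerate):
        warnings.warn(f"degenerate (constant) component(s) {list(degenerate)}; "
                      "their contribution fraction is 0")
    totals = shifted.sum(axis=1)
    fractions = shifted.div(totals.where(totals != 0), axis=0)
    # an individual at the population minimum of every component has an
    # all-zero shifted row; by symmetry give it uniform fractions
    fractions.loc[totals == 0, :] = 1.0 / len(clusters)

    rows = []
    for c in clusters:
        sub = assignment.subgroup(c)
        rem = assignment.remaining(c)
        for comp in clusters:
            rows.append({"subgroup": c, "group": "subgroup", "cluster": comp,
                         "mean": fractions.loc[sub, comp].mean(),
                         "sd": fractions.loc[sub, comp].std()})
            rows.append({"subgroup": c, "group": "remaining", "cluster": comp,
                         "mean": fractions.loc[rem, comp].mean(),
                         "sd": fractions.loc[rem, comp].std()})
    return fractions, pd.DataFrame(rows)


def relative_change(values: pd.Series, assignment: SubgroupAssignment,
                    cluster: str, kind: str = "quantitative") -> float:
    """(L_S − L_R)/SD for a quantitative trait, (P_S − P_R)/SD for a disease.

    L/P are the subgroup and remaining means (prevalences); SD is the
    trait's standard deviation among all high-risk individuals. Undefined
    (NaN, with a warning) when that SD is zero.
    """
    if kind not in ("quantitative", "binary"):
        raise ValueError(f"unknown trait kind {kind!r}")
    vals = values.astype(float)
    hr_idx = assignment.high_risk.index[assignment.high_risk]
    sd = vals.loc[hr_idx].std()
    if not np.isfinite(sd) or sd == 0:
        warnings.warn(f"zero SD among high-risk for {values.name!r}; "
                      "relative change undefined")
        return float("nan")
    mean_s = vals.loc[assignment.subgroup(cluster)].mean()
    mean_r = vals.loc[assignment.remaining(cluster)].mean()
    return float((mean_s - mean_r) / sd)


def relative_change_table(phenotypes: pd.DataFrame, assignment: SubgroupAssignment,
                          traits: list[str] | None = None,
                          kinds: dict[str, str] | None = None) -> pd.DataFrame:
    """Relative change of every trait in every subgroup (long format)."""
    traits = traits if traits is not None else list(phenotypes.columns)
    rows = []
    for cluster in assignment.clusters:
        for trait in traits:
            kind = (kinds or {}).get(trait, "quantitative")
            rows.append({"subgroup": cluster, "trait": trait,
                         "relative_change": relative_change(
                             phenotypes[trait], assignment, cluster, kind=kind)})
    return pd.DataFrame(rows)


def score_phenotype_associations(scores: pd.DataFrame, phenotypes: pd.DataFrame,
                                 covariates: pd.DataFrame | None = None,
                                 binary: dict[str, bool] | None = None,
                                 alpha: float = 0.05) -> pd.DataFrame:
    """Association scan of every score against every phenotype.

    Linear regression for continuous phenotypes, logistic for binary ones,
    adjusting for ``covariates``. Scores are standardized internally. The
    Bonferroni flag uses alpha / (n_phenotypes x n_scores). Non-converged
    fits are flagged rather than raised.
    """
    binary = binary or {}
    n_tests = scores.shape[1] * phenotypes.shape[1]
    bonf = alpha / n_tests
    rows = []
    for s in scores.columns:
        z = (scores[s] - scores[s].mean()) / scores[s].std()
        for ph in phenotypes.columns:
            y = phenotypes[ph]
            exog = pd.DataFrame({"score": z})
            if covariates is not None:
                exog = pd.concat([exog, covariates], axis=1)
            exog = sm.add_constant(exog)
            try:
                if binary.get(ph, False):
                    fit = sm.Logit(y, exog).fit(disp=0, maxiter=200)
                    converged = bool(fit.mle_retvals.get("converged", True))
                else:
                    fit = sm.OLS(y, exog).fit()
                    converged = True
                coef = float(fit.params["score"])
                p = float(fit.pvalues["score"])
            except Exception:
                coef, p, converged = np.nan, np.nan, False
            rows.append({"score": s, "phenotype": ph, "coefficient": coef,
                         "p": p, "converged": converged,
                         "significant": bool(converged and p < bonf)})
    return pd.DataFrame(rows)
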