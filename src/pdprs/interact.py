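"""PRS x trait interaction analysis.

The analysis pipeline: (1) residualize each trait of interest on the PRS
and covariates (linear for continuous traits, logistic for binary ones;
logistic residuals carry a caution flag because response residuals of a
binary variable are not the variable); (2) rank-based inverse normal
transform (Blom offset 3/8, average ranks for ties); (3) test the
PRS x transformed-trait interaction with a 1-df likelihood-ratio test
between nested models, Cox proportional hazards for survival outcomes or
ordinary least squares for continuous ones; (4) Benjamini-Hochberg FDR
across the tested pairs.

For significant pairs, risk among high-genetic-risk individuals is
stratified into the 2x2 of (subgroup vs remaining) x (exposed vs
unexposed): hazard ratios against the remaining-unexposed reference,
absolute risk (AR, proportion of incident cases) per cell, absolute risk
reduction (ARR = AR_exposed − AR_unexposed) per stratum, and the relative
excess risk due to interaction RERI = (ARR_subgroup − ARR_remaining)/R00
with a Delta-method standard error propagating the four cells' binomial
variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class InteractionTest:
    score_id: str
    trait_id: str
    coefficient: float
    lrt: float
    p: float
    converged: bool = True
    q: float = float("nan")


@dataclass
class StratifiedRisk:
    """Risk summary over (subgroup, remaining) x (exposed, unexposed)."""

    counts: pd.DataFrame          # rows: stratum, cols: exposure -> n
    absolute_risk: pd.DataFrame   # same layout -> proportion of cases
    arr_subgroup: float
    arr_remaining: float
    hazard_ratios: pd.DataFrame   # cell vs (remaining, unexposed) reference
    flagged_cells: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class ReriResult:
    reri: float
    se: float
    p: float
    ok: bool = True


def residualize_trait(trait: pd.Series | np.ndarray, covariates: pd.DataFrame,
                      family: str = "linear") -> np.ndarray:
    """Response residuals (observed − fitted mean) after covariate adjustment.

    ``family`` is "linear" (OLS) or "logistic" (binary traits; interpret
    downstream results with caution). A rank-deficient design raises an
    error naming the collinear columns.
    """
    if family not in ("linear", "logistic"):
        raise ValueError(f"unknown family {family!r}")
    y = np.asarray(trait, dtype=float)
    exog = sm.add_constant(covariates.astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(exog.to_numpy())
    if rank < exog.shape[1]:
        bad = []
        for col in covariates.columns:
            sub = exog.drop(columns=[col])
            if np.linalg.matrix_rank(sub.to_numpy()) == rank:
                bad.append(col)
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")
    if family == "logistic":
        fit = sm.Logit(y, exog).fit(disp=0, maxiter=200)
    else:
        fit = sm.OLS(y, exog).fit()
    return y - np.asarray(fit.predict(exog))


def int_transform(values: np.ndarray | pd.Series) -> np.ndarray:
    """Rank-based inverse normal transform, Blom offset:
    Phi^{-1}((r − 3/8)/(n + 1/4)) with average ranks for ties."""
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("inverse normal transform needs >= 2 distinct values")
    r = stats.rankdata(x, method="average")
    return stats.norm.ppf((r - 0.375) / (x.size + 0.25))


def _lrt(ll_full: float, ll_reduced: float) -> tuple[float, float]:
    lrt = max(2.0 * (ll_full - ll_reduced), 0.0)
    return lrt, float(stats.chi2.sf(lrt, df=1))


def interaction_test(prs: pd.Series | np.ndarray,
                     moderator: pd.Series | np.ndarray,
                     outcome: pd.Series | np.ndarray | None = None,
                     time: pd.Series | np.ndarray | None = None,
                     event: pd.Series | np.ndarray | None = None,
                     covariates: pd.DataFrame | None = None,
                     mode: str = "linear",
                     score_id: str = "PRS",
                     trait_id: str = "trait") -> InteractionTest:
    """1-df likelihood-ratio test of the PRS x moderator interaction.

    ``mode="linear"`` fits nested OLS models of a continuous ``outcome``;
    ``mode="survival"`` fits nested Cox models of (``time``, ``event``).
    Non-convergence yields a flagged result instead of an exception.
    """
    df = pd.DataFrame({"prs": np.asarray(prs, float),
                       "mod": np.asarray(moderator, float)})
    df["prs_x_mod"] = df["prs"] * df["mod"]
    if covariates is not None:
        for c in covariates.columns:
            df[c] = np.asarray(covariates[c], float)
    base_cols = [c for c in df.columns if c != "prs_x_mod"]

    try:
        if mode == "linear":
            if outcome is None:
                raise ValueError("linear mode needs an outcome")
            y = np.asarray(outcome, float)
            full = sm.OLS(y, sm.add_constant(df)).fit()
            red = sm.OLS(y, sm.add_constant(df[base_cols])).fit()
            coef = float(full.params["prs_x_mod"])
            lrt, p = _lrt(full.llf, red.llf)
        elif mode == "survival":
            if time is None or event is None:
                raise ValueError("survival mode needs time and event")
            sdf = df.copy()
            sdf["time"] = np.asarray(time, float)
            sdf["event"] = np.asarray(event, float)
            full = CoxPHFitter().fit(sdf, duration_col="time", event_col="event")
            red = CoxPHFitter().fit(sdf[base_cols + ["time", "event"]],
                                    duration_col="time", event_col="event")
            coef = float(full.params_["prs_x_mod"])
            lrt, p = _lrt(full.log_likelihood_, red.log_likelihood_)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    except Exception as exc:
        from lifelines.exceptions import ConvergenceError
        if isinstance(exc, ValueError) and not isinstance(exc, ConvergenceError):
            raise
        # convergence failure / singular fit: flag the pair, don't crash
        return InteractionTest(score_id, trait_id, np.nan, np.nan, np.nan,
                               converged=False)
    return InteractionTest(score_id, trait_id, coef, lrt, p)


def bh_fdr(p_values: np.ndarray | pd.Series,
           level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (q-values, significance flags)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p, p.astype(bool)
    _, q, _, _ = multipletests(p, alpha=level, method="fdr_bh")
    return q, q <= level


def stratified_risk(time: np.ndarray, event: np.ndarray,
                    subgroup: np.ndarray, exposure: np.ndarray,
                    covariates: pd.DataFrame | None = None) -> StratifiedRisk:
    """Four-cell risk comparison among high-risk individuals.

    ``subgroup`` and ``exposure`` are boolean per individual (everyone is
    assumed high-risk). Hazard ratios compare the three non-reference
    cells to (remaining, unexposed); absolute risk is the proportion of
    incident cases per cell; ARR per stratum is AR_exposed − AR_unexposed.
    Empty cells are flagged and excluded from the Cox fit.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    sub = np.asarray(subgroup, bool)
    exp_ = np.asarray(exposure, bool)

    strata = {"subgroup": sub, "remaining": ~sub}
    expo = {"exposed": exp_, "unexposed": ~exp_}
    counts = pd.DataFrame(index=list(strata), columns=list(expo), dtype=float)
    ar = pd.DataFrame(index=list(strata), columns=list(expo), dtype=float)
    flagged = []
    for s, smask in strata.items():
        for e, emask in expo.items():
            cell = smask & emask
            counts.loc[s, e] = cell.sum()
            if cell.sum() == 0:
                flagged.append((s, e))
                ar.loc[s, e] = np.nan
            else:
                ar.loc[s, e] = event[cell].mean()

    arr_sub = float(ar.loc["subgroup", "exposed"] - ar.loc["subgroup", "unexposed"])
    arr_rem = float(ar.loc["remaining", "exposed"] - ar.loc["remaining", "unexposed"])

    cells = pd.Series(np.select(
        [sub & exp_, sub & ~exp_, ~sub & exp_],
        ["subgroup_exposed", "subgroup_unexposed", "remaining_exposed"],
        default="remaining_unexposed"))
    df = pd.get_dummies(cells).drop(columns=["remaining_unexposed"], errors="ignore")
    df = df.astype(float)
    if covariates is not None:
        df = pd.concat([df.reset_index(drop=True),
                        covariates.reset_index(drop=True)], axis=1)
    df["time"], df["event"] = time, event
    hr_rows = []
    try:
        cph = CoxPHFitter().fit(df, duration_col="time", event_col="event")
        for cell in ("subgroup_exposed", "subgroup_unexposed", "remaining_exposed"):
            if cell in cph.params_.index:
                hr_rows.append({
                    "cell": cell,
                    "hr": float(np.exp(cph.params_[cell])),
                    "p": float(cph.summary.loc[cell, "p"]),
                })
            else:
                hr_rows.append({"cell": cell, "hr": np.nan, "p": np.nan})
    except Exception:
        hr_rows = [{"cell": c, "hr": np.nan, "p": np.nan}
                   for c in ("subgroup_exposed", "subgroup_unexposed",
                             "remaining_exposed")]
    return StratifiedRisk(counts=counts, absolute_risk=ar,
                          arr_subgroup=arr_sub, arr_remaining=arr_rem,
                          hazard_ratios=pd.DataFrame(hr_rows),
                          flagged_cells=flagged)


def reri(stratified: StratifiedRisk) -> ReriResult:
    """Relative excess risk due to interaction, with Delta-method SE.

    RERI = (ARR_subgroup − ARR_remaining)/R00 where R00 is the case
    proportion among remaining-unexposed individuals. Writing the four
    cell risks A_se, A_su, A_re, A_ru (= R00), RERI = (A_se − A_su − A_re
    + A_ru)/A_ru; the variance propagates independent binomial cell
    variances A(1−A)/n through the gradient. Two-sided normal p-value.
    """
    a = stratified.absolute_risk
    n = stratified.counts
    a_se, a_su = a.loc["subgroup", "exposed"], a.loc["subgroup", "unexposed"]
    a_re, a_ru = a.loc["remaining", "exposed"], a.loc["remaining", "unexposed"]
    if not np.isfinite(a_ru) or a_ru <= 0:
        return ReriResult(np.nan, np.nan, np.nan, ok=False)
    value = (a_se - a_su - a_re + a_ru) / a_ru
    grads = {
        ("subgroup", "exposed"): 1.0 / a_ru,
        ("subgroup", "unexposed"): -1.0 / a_ru,
        ("remaining", "exposed"): -1.0 / a_ru,
        ("remaining", "unexposed"): -(a_se - a_su - a_re) / a_ru ** 2,
    }
    var = 0.0
    for (s, e), g in grads.items():
        cell_n = n.loc[s, e]
        cell_a = a.loc[s, e]
        if not np.isfinite(cell_a) or cell_n == 0:
            return ReriResult(value, np.nan, np.nan, ok=False)
        var += g ** 2 * cell_a * (1 - cell_a) / cell_n
    se = float(np.sqrt(var))
    p = 2.0 * stats.norm.sf(abs(value) / se) if se > 0 else float("nan")
    return ReriResult(float(value), se, float(p))
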