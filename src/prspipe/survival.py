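"""MCI-to-AD conversion analysis.

MCI participants with at least 12 months of follow-up are stratified by
PRS tertiles computed on the full cohort (CU+MCI+ADD); the 1st (low) and
3rd (high) tertiles are compared with Kaplan–Meier curves, the log-rank
test (PRS group only, no covariates), and a Cox proportional-hazards
model with Efron tie handling and the covariates: age, sex, education,
two ancestry components, and APOE ε4/ε2 allele doses.  The analysis is
additionally run within APOE ε4 carriers and noncarriers separately
(dropping the ε4 covariate within strata).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

from prspipe.errors import DegenerateDataError, PrsPipeError

MIN_FOLLOWUP_MONTHS = 12.0

COX_COVARIATES = ["age", "sex", "education", "pc1", "pc2", "apoe_e4_dose", "apoe_e2_dose"]


@dataclass
class CoxFit:
    """Per-covariate hazard ratios with Wald CIs and p-values.

    ``summary`` columns: hr, ci_low, ci_high, p (NaN rows mark covariates
    that could not be estimated, e.g. monotone likelihood).
    """

    summary: pd.DataFrame
    log_likelihood: float
    n: int
    n_events: int
    ties: str = "efron"
    flagged: list[str] = field(default_factory=list)


def tertile_groups(all_scores: pd.Series, target_ids) -> pd.Series:
    """Label target samples low/mid/high by full-cohort PRS tertiles.

    Cut points are the 1/3 and 2/3 quantiles (linear interpolation) of
    ``all_scores``; values at or below a cut fall in the lower group.
    """
    scores = np.asarray(all_scores, dtype=float)
    if len(scores) < 3:
        raise PrsPipeError("tertiles require at least 3 participants")
    if np.ptp(scores) == 0:
        raise DegenerateDataError("degenerate PRS distribution: no tertiles")
    q1, q2 = np.quantile(scores, [1 / 3, 2 / 3])
    target = all_scores.loc[list(target_ids)]
    labels = np.where(target <= q1, "low", np.where(target <= q2, "mid", "high"))
    return pd.Series(labels, index=target.index, name="prs_group")


def prepare_records(
    pheno: pd.DataFrame,
    prs_group: pd.Series,
    min_followup: float = MIN_FOLLOWUP_MONTHS,
) -> pd.DataFrame:
    """MCI records with follow-up ≥ 12 months, joined with PRS groups."""
    df = pheno[pheno["diagnosis"] == "MCI"].copy()
    df = df[df["followup_months"] >= min_followup]
    if "sex" in df.columns and df["sex"].dtype == object:
        df["sex"] = df["sex"].map({"F": 0, "M": 1})
    df["prs_group"] = prs_group.reindex(df["sample_id"]).to_numpy()
    return df.dropna(subset=["prs_group", "followup_months", "converted"]).reset_index(drop=True)


def km_curve(time, event, level: float = 0.95) -> pd.DataFrame:
    """Kaplan–Meier product-limit estimate with Greenwood-based CIs."""
    kmf = KaplanMeierFitter(alpha=1 - level)
    kmf.fit(np.asarray(time, dtype=float), np.asarray(event, dtype=int))
    ci = kmf.confidence_interval_survival_function_
    out = pd.DataFrame(
        {"time": kmf.survival_function_.index.to_numpy(),
         "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
         "ci_low": ci.iloc[:, 0].to_numpy(), "ci_high": ci.iloc[:, 1].to_numpy()}
    )
    return out


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test (chi-square with 1 df, p-value)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    levels = pd.unique(group)
    if len(levels) != 2:
        raise PrsPipeError(f"log-rank needs exactly 2 groups, got {list(levels)}")
    a, b = group == levels[0], group == levels[1]
    if a.sum() == 0 or b.sum() == 0:
        raise PrsPipeError("one group is empty")
    if event.sum() == 0:
        raise DegenerateDataError("no events observed")
    res = _ll_logrank(time[a], time[b], event_observed_A=event[a], event_observed_B=event[b])
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    records: pd.DataFrame,
    covariates: list[str] | None = None,
    duration_col: str = "followup_months",
    event_col: str = "converted",
    ties: str = "efron",
) -> CoxFit:
    """Cox proportional-hazards fit (partial likelihood, Efron ties).

    ``prs_group`` is encoded high=1 / low=0 if present among the
    covariates.  Covariates that are constant (or constant among events —
    monotone likelihood) are flagged and reported as NA rows, mirroring
    how such cells are left blank in stratified analyses.
    """
    covariates = list(covariates if covariates is not None else ["prs_high"] + COX_COVARIATES)
    df = records.copy()
    if "prs_group" in df.columns and "prs_high" in covariates:
        df = df[df["prs_group"].isin(["low", "high"])].copy()
        df["prs_high"] = (df["prs_group"] == "high").astype(float)
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise PrsPipeError(f"records lack covariate columns {missing}")
    n_events = int(df[event_col].sum())
    if n_events == 0:
        raise DegenerateDataError("Cox model requires at least one event")

    flagged = [c for c in covariates if df[c].nunique(dropna=True) < 2]
    usable = [c for c in covariates if c not in flagged]
    model_df = df[[duration_col, event_col] + usable].dropna()
    cph = CoxPHFitter()
    try:
        import warnings

        with np.errstate(over="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")  # lifelines flags near-monotone likelihoods
            cph.fit(model_df, duration_col=duration_col, event_col=event_col)
            summ = cph.summary
            rows = {
                c: {"hr": float(np.exp(summ.loc[c, "coef"])),
                    "ci_low": float(np.exp(summ.loc[c, "coef lower 95%"])),
                    "ci_high": float(np.exp(min(summ.loc[c, "coef upper 95%"], 700.0))),
                    "p": float(summ.loc[c, "p"])}
                for c in usable
            }
            ll = float(cph.log_likelihood_)
    except ConvergenceError as exc:
        flagged = flagged + usable
        rows, ll = {}, np.nan
    na_row = {"hr": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan}
    summary = pd.DataFrame(
        {c: rows.get(c, na_row) for c in covariates}
    ).T[["hr", "ci_low", "ci_high", "p"]]
    summary.index.name = "covariate"
    return CoxFit(summary=summary, log_likelihood=ll, n=len(model_df),
                  n_events=n_events, ties=ties, flagged=flagged)


def stratified_conversion(records: pd.DataFrame) -> dict[str, dict]:
    """Run the conversion analysis within ε4 carriers and noncarriers.

    The ε4 dose covariate is dropped within strata (it is constant or
    near-constant there).  Returns per-stratum Cox fits and log-rank
    results keyed by 'carrier' and 'noncarrier'.
    """
    if "apoe_e4_dose" not in records.columns:
        raise PrsPipeError("records lack apoe_e4_dose")
    strata = {
        "noncarrier": records[records["apoe_e4_dose"] == 0],
        "carrier": records[records["apoe_e4_dose"] > 0],
    }
    if strata["noncarrier"].empty or strata["carrier"].empty:
        empty = [k for k, v in strata.items() if v.empty]
        raise PrsPipeError(f"empty APOE stratum: {empty}")
    covs = ["prs_high"] + [c for c in COX_COVARIATES if c != "apoe_e4_dose"]
    out = {}
    for name, sub in strata.items():
        entry: dict = {"n": len(sub), "n_events": int(sub["converted"].sum())}
        hl = sub[sub["prs_group"].isin(["low", "high"])]
        try:
            entry["cox"] = cox_fit(sub, covariates=covs)
        except (DegenerateDataError, PrsPipeError) as exc:
            entry["cox"] = None
            entry["flag"] = str(exc)
        try:
            chi2, p = logrank_test(
                hl["followup_months"], hl["converted"], hl["prs_group"]
            )
            entry["logrank"] = {"chi2": chi2, "p": p}
        except (DegenerateDataError, PrsPipeError) as exc:
            entry["logrank"] = None
            entry.setdefault("flag", str(exc))
        out[name] = entry
    return out
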