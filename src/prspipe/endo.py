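"""Endophenotype association with the standardized PRS.

Three nested covariate models are fitted per outcome and subject group:

* Model 1: age, sex, education, first two ancestry components
* Model 2: Model 1 + APOE ε4 dose
* Model 3: Model 2 + APOE ε2 dose

Continuous outcomes (CSF ratios, volumes, neuropsychological scores) use
OLS; binary imaging status (FDG N1/P1, PiB ±) uses logistic regression.
The Wald p for the PRS slope is reported, and p-values are BH-FDR
corrected within each subject-group stratum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from prspipe.errors import PrsPipeError

MODEL_COVARIATES = {
    1: ["age", "sex", "education", "pc1", "pc2"],
    2: ["age", "sex", "education", "pc1", "pc2", "apoe_e4_dose"],
    3: ["age", "sex", "education", "pc1", "pc2", "apoe_e4_dose", "apoe_e2_dose"],
}


@dataclass
class AssociationResult:
    outcome: str
    group: str
    model_id: int
    beta: float
    p: float
    n: int
    fdr_q: float = np.nan
    link: str = "linear"


def _check_collinear(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        # name columns whose removal restores full rank
        offending = [
            c for c in X.columns
            if np.linalg.matrix_rank(X.drop(columns=c).to_numpy(dtype=float))
            == np.linalg.matrix_rank(arr)
        ]
        raise PrsPipeError(f"collinear design; offending columns: {offending}")


def fit_linear(
    outcome, prs, covariates: pd.DataFrame, binary: bool | None = None
) -> tuple[float, float, int]:
    """Slope of the standardized PRS on an outcome, adjusting covariates.

    Returns (beta, Wald p, n complete cases).  ``binary=None`` detects a
    0/1 outcome and switches to logistic regression.
    """
    df = pd.DataFrame(covariates).copy()
    df.insert(0, "prs", np.asarray(prs, dtype=float))
    df.insert(0, "outcome", np.asarray(outcome, dtype=float))
    df = df.dropna()
    n = len(df)
    if n < df.shape[1] + 1:
        raise PrsPipeError(f"too few complete cases ({n}) for {df.shape[1] - 1} terms")
    y = df.pop("outcome")
    X = sm.add_constant(df, has_constant="add")
    _check_collinear(X)
    if binary is None:
        binary = set(np.unique(y)) <= {0.0, 1.0}
    model = sm.Logit(y, X) if binary else sm.OLS(y, X)
    res = model.fit(disp=0) if binary else model.fit()
    return float(res.params["prs"]), float(res.pvalues["prs"]), n


def bh_fdr(p_values, groups=None) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, applied within each group
    stratum independently when ``groups`` is given."""
    p = np.asarray(p_values, dtype=float)
    q = np.empty_like(p)
    if groups is None:
        groups = np.zeros(len(p))
    groups = np.asarray(groups)
    for g in pd.unique(groups):
        mask = groups == g
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def associate(
    pheno: pd.DataFrame,
    prs: pd.Series,
    outcomes: list[str],
    groups: tuple[str, ...] = ("All", "CU", "MCI", "ADD"),
    models: tuple[int, ...] = (1, 2, 3),
    binary_outcomes: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Full association table: every outcome × group × model, FDR within
    each (group, model) stratum."""
    rows = []
    df = pheno.copy()
    if "sex" in df.columns and df["sex"].dtype == object:
        df["sex"] = df["sex"].map({"F": 0, "M": 1})
    df["prs"] = prs.reindex(df["sample_id"]).to_numpy()
    for group in groups:
        sub = df if group == "All" else df[df["diagnosis"] == group]
        for model_id in models:
            cov_cols = MODEL_COVARIATES[model_id]
            for outcome in outcomes:
                cols = [outcome, "prs"] + cov_cols
                avail = sub.dropna(subset=[c for c in cols if c in sub.columns])
                try:
                    beta, p, n = fit_linear(
                        avail[outcome], avail["prs"], avail[cov_cols],
                        binary=(outcome in binary_outcomes) or None,
                    )
                except PrsPipeError:
                    beta, p, n = np.nan, np.nan, len(avail)
                rows.append(
                    {"outcome": outcome, "group": group, "model_id": model_id,
                     "beta": beta, "p": p, "n": n}
                )
    table = pd.DataFrame(rows)
    table["fdr_q"] = np.nan
    for (group, model_id), idx in table.groupby(["group", "model_id"]).groups.items():
        ok = table.loc[idx, "p"].notna()
        good = idx[ok]
        if len(good):
            table.loc[good, "fdr_q"] = bh_fdr(table.loc[good, "p"])
    return table


def decile_summary(prs, outcome) -> pd.DataFrame:
    """Per-decile outcome summaries (mean, SD, n); PRS ranks assign the
    deciles, ties go to the lower decile."""
    prs = np.asarray(prs, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    n = len(prs)
    if n < 10:
        raise PrsPipeError("decile summary requires n >= 10")
    r = rankdata(prs, method="min")  # ties share the lower decile
    decile = ((r - 1) * 10 // n).astype(int) + 1
    df = pd.DataFrame({"decile": decile, "outcome": outcome, "prs": prs})
    out = (
        df.groupby("decile")
        .agg(
            prs_mean=("prs", "mean"),
            outcome_mean=("outcome", "mean"),
            outcome_sd=("outcome", lambda x: x.std(ddof=1)),
            n=("outcome", "size"),
        )
        .reset_index()
    )
    return out
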