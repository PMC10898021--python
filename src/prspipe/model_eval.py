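"""Prediction-model machinery for case-control PRS evaluation.

Nagelkerke's pseudo-R² compares a full logistic model (PRS + two
ancestry components) against a null model (components only); the p_T
maximizing the difference ΔR² is the selected threshold.  Discrimination
is summarized by the AUC with DeLong structural-component variance and
95% CIs, correlated AUCs are compared with the paired DeLong test, and
generalization is checked by stratified fivefold cross-validation and by
freezing coefficients and applying them to an external cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold

from prspipe.errors import DegenerateDataError, PrsPipeError


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit (unpenalized, IRLS via statsmodels)."""

    params: pd.Series
    llf: float
    n: int
    converged: bool
    pvalues: pd.Series
    bse: pd.Series
    separation: bool = False
    ll_intercept_only: float = np.nan

    def predict_linear(self, X: pd.DataFrame) -> np.ndarray:
        """Linear predictor for a design with the same columns."""
        missing = [c for c in self.params.index if c not in X.columns]
        if missing:
            raise PrsPipeError(f"new data lacks model columns {missing}")
        return X[self.params.index].to_numpy() @ self.params.to_numpy()


@dataclass
class ModelComparison:
    """Nagelkerke R² of nested logistic models at one p_T."""

    r2_full: float
    r2_null: float
    p_value: float
    p_threshold: float = np.nan
    n_snps: int = 0

    @property
    def delta_r2(self) -> float:
        return self.r2_full - self.r2_null


@dataclass
class ROCResult:
    """AUC with DeLong variance and 95% normal-approximation CI."""

    auc: float
    ci_low: float
    ci_high: float
    variance: float


def _design(X: pd.DataFrame | np.ndarray, add_intercept: bool = True) -> pd.DataFrame:
    X = pd.DataFrame(X).copy()
    if add_intercept and "const" not in X.columns:
        X.insert(0, "const", 1.0)
    return X


def fit_logistic(y, X, add_intercept: bool = True) -> LogisticFit:
    """Unpenalized ML logistic regression with Wald p-values.

    Perfect separation is flagged (coefficients still reported); a
    rank-deficient design raises.
    """
    X = _design(X, add_intercept)
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("y must be binary 0/1")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise PrsPipeError("design matrix is rank deficient")
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except (np.linalg.LinAlgError, Exception) as exc:
            # Newton fails on strict separation (singular Hessian); fall
            # back to a gradient method and flag below
            res = sm.Logit(y, X).fit(disp=0, maxiter=500, method="bfgs")
        for w in caught:
            if "erfect" in str(w.message) or "separ" in str(w.message).lower():
                separation = True
    # strict separation: every case's linear predictor exceeds every control's
    lp = X.to_numpy() @ res.params.to_numpy()
    if len(np.unique(y)) == 2 and lp[y == 1].min() > lp[y == 0].max():
        separation = True
    return LogisticFit(
        params=res.params, llf=float(res.llf), n=len(y),
        converged=bool(res.mle_retvals.get("converged", True)),
        pvalues=res.pvalues, bse=res.bse, separation=separation,
        ll_intercept_only=_intercept_only_llf(y),
    )


def _intercept_only_llf(y: np.ndarray) -> float:
    p = y.mean()
    if p in (0.0, 1.0):
        return 0.0
    n = len(y)
    return n * (p * np.log(p) + (1 - p) * np.log(1 - p))


def nagelkerke_r2(
    full: LogisticFit, null: LogisticFit, baseline: str = "intercept"
) -> ModelComparison:
    """Nagelkerke R² for a nested model pair sharing the same y.

    Per model: Cox–Snell R² = 1 − exp((2/n)(LL0 − LLm)), rescaled by its
    maximum 1 − exp((2/n)·LL0).  ``baseline='intercept'`` takes LL0 from
    the intercept-only model (the common C+T scoring-tool convention);
    ``baseline='null'``
    uses the null model's own likelihood.
    """
    if full.n != null.n:
        raise PrsPipeError(f"model n mismatch: {full.n} vs {null.n}")
    extra = [c for c in null.params.index if c not in full.params.index]
    if extra:
        raise PrsPipeError(f"null model columns {extra} absent from full model")
    n = full.n
    if baseline == "intercept":
        ll0 = full.ll_intercept_only
        if not np.isfinite(ll0):
            raise PrsPipeError("intercept baseline requires fits made by fit_logistic")
    elif baseline == "null":
        ll0 = null.llf
    else:
        raise ValueError("baseline must be 'intercept' or 'null'")

    def nk(llm: float) -> float:
        cs = 1.0 - np.exp((2.0 / n) * (ll0 - llm))
        denom = 1.0 - np.exp((2.0 / n) * ll0)
        return float(cs / denom) if denom > 0 else 0.0

    prs_cols = [c for c in full.params.index if c not in null.params.index]
    p = float(full.pvalues[prs_cols[0]]) if prs_cols else 1.0
    return ModelComparison(r2_full=nk(full.llf), r2_null=nk(null.llf), p_value=p)


def nested_r2(
    y, full_X: pd.DataFrame, null_cols: list[str], baseline: str = "intercept"
) -> ModelComparison:
    """Fit full and null logistic models and return the Nagelkerke pair.

    The null model uses ``null_cols`` of ``full_X``; an intercept is
    always included in both.
    """
    y = np.asarray(y, dtype=float)
    full = fit_logistic(y, full_X)
    if null_cols:
        null = fit_logistic(y, full_X[null_cols])
    else:
        ll0 = _intercept_only_llf(y)
        p = y.mean()
        null = LogisticFit(
            params=pd.Series({"const": np.log(p / (1 - p)) if 0 < p < 1 else 0.0}),
            llf=ll0, n=len(y), converged=True,
            pvalues=pd.Series({"const": np.nan}), bse=pd.Series({"const": np.nan}),
            ll_intercept_only=ll0,
        )
    return nagelkerke_r2(full, null, baseline=baseline)


def select_threshold(
    grid,
    scores_by_pt: dict[float, pd.Series],
    y,
    components: pd.DataFrame,
    n_snps_by_pt: dict[float, int] | None = None,
    baseline: str = "intercept",
) -> tuple[pd.DataFrame, float]:
    """Scan the p_T grid and pick the threshold maximizing ΔR².

    For each threshold with a defined score, the full model is
    PRS + the two ancestry components, the null model the components
    alone.  Returns the grid table (one row per p_T) and the argmax p_T.
    """
    rows = []
    y = np.asarray(y, dtype=float)
    comp_cols = list(components.columns)
    for pt in grid:
        if pt not in scores_by_pt:
            continue
        X = components.copy()
        X.insert(0, "prs", np.asarray(scores_by_pt[pt], dtype=float))
        mc = nested_r2(y, X, comp_cols, baseline=baseline)
        rows.append(
            {"p_threshold": pt, "r2_full": mc.r2_full, "r2_null": mc.r2_null,
             "delta_r2": mc.delta_r2, "p_value": mc.p_value,
             "n_snps": (n_snps_by_pt or {}).get(pt, 0)}
        )
    if not rows:
        raise DegenerateDataError("no threshold produced a non-empty score")
    table = pd.DataFrame(rows)
    best = float(table.loc[table["delta_r2"].idxmax(), "p_threshold"])
    return table, best


# ---------------------------------------------------------------------------
# DeLong machinery


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, y: np.ndarray):
    """Structural components V10 (cases) and V01 (controls) and the AUC."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise DegenerateDataError("both classes required for ROC analysis")
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r, neg_r = all_r[:m], all_r[m:]
    auc = (pos_r.sum() - m * (m + 1) / 2) / (m * n)
    v10 = (pos_r - _midrank(pos)) / n
    v01 = 1.0 - (neg_r - _midrank(neg)) / m
    return auc, v10, v01


def roc_auc_delong(scores, y, level: float = 0.95) -> ROCResult:
    """AUC (Mann–Whitney, ties at 0.5) with DeLong variance and CI."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    auc, v10, v01 = _delong_components(scores, y)
    var = np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01)
    z = sps.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return ROCResult(
        auc=float(auc), ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)), variance=float(var),
    )


def delong_paired_test(scores_a, scores_b, y) -> float:
    """Two-sided paired DeLong test for two correlated AUCs on the same y."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    y = np.asarray(y, dtype=int)
    if scores_a.shape != scores_b.shape or scores_a.shape != y.shape:
        raise ValueError("paired test requires equal-length score vectors and y")
    auc_a, v10_a, v01_a = _delong_components(scores_a, y)
    auc_b, v10_b, v01_b = _delong_components(scores_b, y)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    s = s10 / m + s01 / n
    var_diff = s[0, 0] + s[1, 1] - 2 * s[0, 1]
    if var_diff <= 0:
        if auc_a == auc_b:
            return 1.0
        raise DegenerateDataError("zero variance of the AUC difference")
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    return float(2 * sps.norm.sf(abs(z)))


def kfold_cv(y, X, k: int = 5, seed: int = 0) -> dict:
    """Stratified k-fold CV of a logistic model; per-fold and pooled AUC."""
    X = _design(X)
    y = np.asarray(y, dtype=int)
    if len(y) < k:
        raise ValueError(f"n={len(y)} < k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_aucs, pooled_scores, pooled_y = [], [], []
    for train, test in skf.split(X, y):
        if len(np.unique(y[train])) < 2:
            raise DegenerateDataError("a training fold lost one class")
        fit = fit_logistic(y[train], X.iloc[train], add_intercept=False)
        lp = fit.predict_linear(X.iloc[test])
        if len(np.unique(y[test])) == 2:
            fold_aucs.append(roc_auc_delong(lp, y[test]).auc)
        pooled_scores.append(lp)
        pooled_y.append(y[test])
    pooled = roc_auc_delong(np.concatenate(pooled_scores), np.concatenate(pooled_y))
    return {
        "fold_aucs": fold_aucs,
        "mean_auc": float(np.mean(fold_aucs)),
        "sd_auc": float(np.std(fold_aucs, ddof=1)) if len(fold_aucs) > 1 else 0.0,
        "pooled": pooled,
    }


def apply_model(fit: LogisticFit, y_new, X_new, add_intercept: bool = True) -> ROCResult:
    """Freeze the coefficients and measure discrimination in a new cohort."""
    X_new = _design(X_new, add_intercept)
    lp = fit.predict_linear(X_new)
    return roc_auc_delong(lp, np.asarray(y_new, dtype=int))


def tukey_hsd(values, groups) -> pd.DataFrame:
    """Tukey honestly-significant-difference pairwise comparisons.

    Returns one row per group pair with the mean difference and the
    studentized-range adjusted p-value.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("Tukey HSD requires at least two groups")
    samples = [values[groups == lv] for lv in levels]
    for lv, s in zip(levels, samples):
        if len(s) < 2:
            raise DegenerateDataError(f"group {lv!r} has fewer than 2 observations")
    res = sps.tukey_hsd(*samples)
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            rows.append(
                {"group_a": levels[i], "group_b": levels[j],
                 "mean_diff": float(np.mean(samples[i]) - np.mean(samples[j])),
                 "p_adj": float(res.pvalue[i, j])}
            )
    return pd.DataFrame(rows)
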