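"""Logistic fits, Nagelkerke R², DeLong AUC machinery, CV, Tukey HSD."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from prspipe.errors import DegenerateDataError, PrsPipeError
from prspipe.model_eval import (
    _design,
    apply_model,
    delong_paired_test,
    fit_logistic,
    kfold_cv,
    nagelkerke_r2,
    nested_r2,
    roc_auc_delong,
    select_threshold,
    tukey_hsd,
)


def newton_logistic_oracle(y, X, tol=1e-12):
    """Independent Newton–Raphson logistic solver (hand-rolled)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    b = np.zeros(X.shape[1])
    for _ in range(100):
        mu = 1 / (1 + np.exp(-X @ b))
        w = mu * (1 - mu)
        step = np.linalg.solve((X * w[:, None]).T @ X, X.T @ (y - mu))
        b += step
        if np.max(np.abs(step)) < tol:
            break
    ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    return b, ll


def auc_concordance_oracle(scores, y):
    """Exhaustive pairwise concordance: ties credit 0.5."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else 0.5 if a == b else 0.0
    return total / (len(pos) * len(neg))


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        fit = fit_logistic(y, pd.DataFrame(index=range(100)))
        assert fit.params["const"] == pytest.approx(np.log(0.3 / 0.7), abs=1e-8)

    def test_matches_newton_oracle_on_textbook_fixture(self):
        y = np.array([0, 0, 1, 0, 1, 1])
        x = np.array([-2.0, -1.0, 0.0, 0.5, 1.0, 2.0])
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        b, ll = newton_logistic_oracle(y, np.column_stack([np.ones(6), x]))
        np.testing.assert_allclose(fit.params.to_numpy(), b, atol=1e-8)
        assert fit.llf == pytest.approx(ll, abs=1e-8)

    def test_null_predictor_small_z(self, rng):
        y = rng.integers(0, 2, 1000)
        x = rng.normal(size=1000)
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        z = fit.params["x"] / fit.bse["x"]
        assert abs(z) < 3

    def test_separation_flagged(self):
        y = np.r_[np.zeros(10), np.ones(10)]
        x = np.r_[np.arange(10), np.arange(100, 110)].astype(float)
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        assert fit.separation

    def test_rank_deficient_raises(self):
        y = np.array([0, 1, 0, 1])
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(PrsPipeError, match="rank"):
            fit_logistic(y, X)


class TestNagelkerke:
    def test_full_equals_null_gives_zero_delta(self, rng):
        y = rng.integers(0, 2, 50)
        x = rng.normal(size=50)
        X = pd.DataFrame({"x": x})
        mc = nested_r2(y, X, ["x"])
        assert mc.delta_r2 == pytest.approx(0.0, abs=1e-10)

    def test_near_perfect_predictor_approaches_one(self):
        n = 200
        x = np.linspace(-3, 3, n)
        y = (x > 0).astype(float)
        x_jit = x + np.where(np.abs(x) < 0.05, 0.2, 0.0)  # nudge off separation
        mc = nested_r2(y, pd.DataFrame({"x": x_jit}), [])
        assert mc.r2_full > 0.95

    def test_matches_hand_formula_from_oracle_lls(self, rng):
        """Nagelkerke pair recomputed from an independent Newton solver's
        log-likelihoods agrees to 1e-8."""
        n = 20
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = (x1 + rng.normal(size=n) > 0).astype(float)
        X = pd.DataFrame({"x1": x1, "x2": x2})
        mc = nested_r2(y, X, ["x2"])
        _, ll_full = newton_logistic_oracle(y, np.column_stack([np.ones(n), x1, x2]))
        _, ll_null = newton_logistic_oracle(y, np.column_stack([np.ones(n), x2]))
        _, ll0 = newton_logistic_oracle(y, np.ones((n, 1)))

        def nk(llm):
            cs = 1 - np.exp(2 / n * (ll0 - llm))
            return cs / (1 - np.exp(2 / n * ll0))

        assert mc.r2_full == pytest.approx(nk(ll_full), abs=1e-8)
        assert mc.r2_null == pytest.approx(nk(ll_null), abs=1e-8)

    def test_invariant_to_affine_predictor_rescaling(self, rng):
        n = 100
        x = rng.normal(size=n)
        y = (x + rng.normal(size=n) > 0).astype(float)
        a = nested_r2(y, pd.DataFrame({"x": x}), [])
        b = nested_r2(y, pd.DataFrame({"x": 17.0 * x - 3.0}), [])
        assert a.r2_full == pytest.approx(b.r2_full, abs=1e-8)

    def test_mismatched_n_raises(self, rng):
        y1 = rng.integers(0, 2, 30)
        y2 = rng.integers(0, 2, 40)
        f1 = fit_logistic(y1, pd.DataFrame({"x": rng.normal(size=30)}))
        f2 = fit_logistic(y2, pd.DataFrame({"x": rng.normal(size=40)}))
        with pytest.raises(PrsPipeError, match="mismatch"):
            nagelkerke_r2(f1, f2)


class TestSelectThreshold:
    def test_single_threshold_is_argmax(self, rng):
        y = rng.integers(0, 2, 60)
        comps = pd.DataFrame({"pc1": rng.normal(size=60), "pc2": rng.normal(size=60)})
        table, best = select_threshold(
            [0.05], {0.05: pd.Series(rng.normal(size=60))}, y, comps
        )
        assert best == 0.05 and len(table) == 1

    def test_null_removal_reproduces_null_fit(self, rng):
        """Dropping the PRS column from the full design reproduces the
        null model's Nagelkerke R² exactly."""
        n = 120
        y = rng.integers(0, 2, n)
        comps = pd.DataFrame({"pc1": rng.normal(size=n), "pc2": rng.normal(size=n)})
        s = pd.Series(rng.normal(size=n))
        table, _ = select_threshold([0.5], {0.5: s}, y, comps)
        null_direct = nested_r2(y, comps, [])
        # the full/null share the same covariate-only null fit
        assert table["r2_null"].iloc[0] == pytest.approx(null_direct.r2_full, abs=1e-10)

    def test_pure_noise_weights_small_delta(self, rng):
        n = 1000
        y = rng.integers(0, 2, n)
        comps = pd.DataFrame({"pc1": rng.normal(size=n), "pc2": rng.normal(size=n)})
        grid = [1e-3, 0.05, 1.0]
        scores = {pt: pd.Series(rng.normal(size=n)) for pt in grid}
        table, _ = select_threshold(grid, scores, y, comps)
        assert table["delta_r2"].max() < 0.02


class TestDeLong:
    def test_perfect_separation_auc_one(self):
        assert roc_auc_delong([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]).auc == 1.0

    def test_all_ties_auc_half(self):
        assert roc_auc_delong([5.0] * 8, [0, 1] * 4).auc == 0.5

    def test_matches_concordance_oracle(self, rng):
        scores = rng.choice([0.1, 0.2, 0.3, 0.4], size=10)
        y = np.r_[np.ones(4), np.zeros(6)].astype(int)
        got = roc_auc_delong(scores, y).auc
        assert got == auc_concordance_oracle(scores, y)

    def test_variance_close_to_bootstrap(self, rng):
        n = 200
        y = rng.integers(0, 2, n)
        scores = rng.normal(size=n) + 0.8 * y
        res = roc_auc_delong(scores, y)
        boots = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            if len(np.unique(y[idx])) < 2:
                continue
            boots.append(roc_auc_delong(scores[idx], y[idx]).auc)
        bvar = np.var(boots, ddof=1)
        assert res.variance == pytest.approx(bvar, rel=0.15)

    def test_one_class_raises(self):
        with pytest.raises(DegenerateDataError):
            roc_auc_delong([1, 2, 3], [1, 1, 1])

    def test_paired_identical_scores_p_one(self, rng):
        y = rng.integers(0, 2, 40)
        s = rng.normal(size=40)
        assert delong_paired_test(s, s, y) == 1.0

    def test_paired_informative_vs_noise_significant(self, rng):
        n = 500
        y = rng.integers(0, 2, n)
        informative = y + rng.normal(0, 0.7, n)
        noise = rng.normal(size=n)
        assert delong_paired_test(informative, noise, y) < 0.01


class TestKFoldCV:
    def test_fold_sizes_for_504(self, rng):
        y = np.r_[np.ones(150), np.zeros(354)].astype(int)
        rng.shuffle(y)
        X = pd.DataFrame({"x": rng.normal(size=504)})
        out = kfold_cv(y, X, k=5, seed=1)
        assert len(out["fold_aucs"]) == 5

    def test_deterministic_given_seed(self, rng):
        y = rng.integers(0, 2, 100)
        X = pd.DataFrame({"x": rng.normal(size=100)})
        a = kfold_cv(y, X, k=5, seed=3)
        b = kfold_cv(y, X, k=5, seed=3)
        assert a["fold_aucs"] == b["fold_aucs"]

    def test_cv_auc_not_above_resubstitution_on_average(self, rng):
        diffs = []
        for _ in range(30):
            n = 150
            x = rng.normal(size=n)
            y = (x + rng.normal(0, 2.0, size=n) > 0).astype(int)
            X = pd.DataFrame({"x": x, "noise": rng.normal(size=n)})
            fit = fit_logistic(y, X)
            resub = roc_auc_delong(fit.predict_linear(_design(X)), y).auc
            cv = kfold_cv(y, X, k=5, seed=0)["pooled"].auc
            diffs.append(resub - cv)
        assert np.mean(diffs) >= 0


class TestApplyModel:
    def test_training_cohort_reproduces_training_auc(self, rng):
        n = 200
        X = pd.DataFrame({"x": rng.normal(size=n)})
        y = (X["x"] + rng.normal(size=n) > 0).astype(int)
        fit = fit_logistic(y, X)
        roc_train = roc_auc_delong(fit.predict_linear(_design(X)), y)
        roc_applied = apply_model(fit, y, X)
        assert roc_applied.auc == roc_train.auc

    def test_shuffled_labels_near_half(self, rng):
        n = 2000
        X = pd.DataFrame({"x": rng.normal(size=n)})
        y = (X["x"] + rng.normal(size=n) > 0).astype(int)
        fit = fit_logistic(y, X)
        y_shuf = rng.permutation(y)
        assert abs(apply_model(fit, y_shuf, X).auc - 0.5) < 0.05

    def test_monotone_transform_preserves_auc(self, rng):
        n = 100
        X = pd.DataFrame({"x": rng.normal(size=n)})
        y = rng.integers(0, 2, n)
        fit = fit_logistic(y, X)
        lp = fit.predict_linear(_design(X))
        assert roc_auc_delong(np.exp(lp), y).auc == roc_auc_delong(lp, y).auc


class TestTukeyHSD:
    def test_identical_groups_p_near_one(self, rng):
        v = rng.normal(size=60)
        out = tukey_hsd(np.r_[v, v], np.r_[["a"] * 60, ["b"] * 60])
        assert out["p_adj"].iloc[0] > 0.99

    def test_shifted_group_detected(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(0, 1, 50)
        c = rng.normal(3, 1, 50)
        out = tukey_hsd(np.r_[a, b, c], np.r_[["a"] * 50, ["b"] * 50, ["c"] * 50])
        p_ac = out.set_index(["group_a", "group_b"]).loc[("a", "c"), "p_adj"]
        assert p_ac < 0.001

    def test_two_groups_equal_t_test_via_studentized_range(self, rng):
        """With exactly 2 groups, Tukey p equals the two-sample t-test p
        through q = √2·|t| on N−2 df (closed-form relation)."""
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.7, 1, 25)
        out = tukey_hsd(np.r_[a, b], np.r_[["a"] * 20, ["b"] * 25])
        t, _ = sps.ttest_ind(a, b)
        q = np.sqrt(2) * abs(t)
        p_expected = sps.studentized_range.sf(q, 2, len(a) + len(b) - 2)
        assert out["p_adj"].iloc[0] == pytest.approx(p_expected, abs=1e-6)

    def test_singleton_group_raises(self):
        with pytest.raises(DegenerateDataError):
            tukey_hsd([1.0, 2.0, 3.0], ["a", "a", "b"])
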