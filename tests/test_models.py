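import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iish import (
    ARCG_PFS,
    CCG_PFS,
    IRCG_PFS,
    ClassifierProtocol,
    CutpointConfig,
    ElasticNetConfig,
    ProtocolError,
    ScoreCoefficients,
    ValidationError,
    compare_classifiers,
    correlation_screen,
    evaluate_score,
    find_cutpoint,
    fit_linear_risk_score,
    kaplan_meier_by_group,
    scanner_robustness_screen,
    smote_oversample,
    survival_association,
    train_platinum_classifier,
)

UNIT_VARS = {
    "cluDiss": 1.0, "age": 1.0, "CNB": 1.0, "sites": 1.0, "resection": 1.0,
    "SZN": 1.0, "coarseness": 1.0, "sobel.mean": 1.0,
    "gabor(45,2).kurtosis": 1.0, "gabor(90,2).mean": 1.0,
    "gabor(90,2).skewness": 1.0, "gabor(135,2).mean": 1.0,
}


class TestRiskScores:
    def test_zero_inputs_give_zero(self):
        assert evaluate_score(IRCG_PFS, {k: 0.0 for k in UNIT_VARS}).value == 0.0

    def test_unit_inputs_sum_printed_coefficients(self):
        assert evaluate_score(IRCG_PFS, UNIT_VARS).value == pytest.approx(10.27)
        assert evaluate_score(CCG_PFS, UNIT_VARS).value == pytest.approx(6.115)
        assert evaluate_score(ARCG_PFS, UNIT_VARS).value == pytest.approx(11.61)

    def test_cohort_median_inputs(self):
        # typical-patient arithmetic: 4.44*68.62 + 3.72*59 + 2.11*0.546
        rs = evaluate_score(IRCG_PFS, {"cluDiss": 68.62, "age": 59.0, "CNB": 0.546})
        assert rs.value == pytest.approx(525.30, abs=0.01)

    def test_boundary_score_is_high_risk(self):
        cut = CutpointConfig("iRCG", cutoff=642.00)
        v = {"cluDiss": 0.0, "age": 0.0, "CNB": 0.0}
        at = evaluate_score(IRCG_PFS, {**v, "age": 642.0 / 3.72}, cutpoint=cut)
        assert at.value == pytest.approx(642.00)
        assert at.risk_group == "high"
        below = evaluate_score(IRCG_PFS, {**v, "age": 641.0 / 3.72}, cutpoint=cut)
        assert below.risk_group == "low"

    def test_missing_variable_named_in_error(self):
        with pytest.raises(ValidationError, match="cluDiss"):
            evaluate_score(IRCG_PFS, {"age": 1.0, "CNB": 1.0})

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(-5, 5, allow_nan=False))
    def test_exact_linearity(self, seed, a):
        rng = np.random.default_rng(seed)
        names = list("vwxyz")
        coeffs = ScoreCoefficients("t", dict(zip(names, rng.normal(size=5))))
        x = dict(zip(names, rng.normal(size=5)))
        y = dict(zip(names, rng.normal(size=5)))
        sx = evaluate_score(coeffs, x).value
        sy = evaluate_score(coeffs, y).value
        s_ax = evaluate_score(coeffs, {k: a * v for k, v in x.items()}).value
        s_sum = evaluate_score(coeffs, {k: x[k] + y[k] for k in names}).value
        assert s_ax == pytest.approx(a * sx, rel=1e-9, abs=1e-9)
        assert s_sum == pytest.approx(sx + sy, rel=1e-9, abs=1e-9)


class TestElasticNet:
    def test_support_recovery_on_sparse_signal(self):
        hits = 0
        for s in range(25):
            rng = np.random.default_rng(s)
            X = pd.DataFrame(
                rng.normal(size=(60, 10)), columns=[f"f{i}" for i in range(10)]
            )
            y = 3 * X["f0"] + rng.normal(0, 0.5, 60)
            c = fit_linear_risk_score(X, y, ElasticNetConfig(alpha=1.0, lam=0.2, seed=s))
            nz = {k for k, v in c.coefficients.items() if abs(v) > 1e-8}
            noise_excluded = sum(1 for i in range(1, 10) if f"f{i}" not in nz)
            hits += "f0" in nz and noise_excluded >= 7
        assert hits >= 23  # >= 90% of 25 seeded runs

    def test_full_shrinkage_limit(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        y = X["a"] + rng.normal(size=30)
        c = fit_linear_risk_score(X, y, ElasticNetConfig(alpha=1.0, lam=1e9))
        assert all(v == 0.0 for v in c.coefficients.values())

    def test_lasso_keeps_one_of_duplicated_features(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        X["a_copy"] = X["a"]
        y = 2 * X["a"] + rng.normal(0, 0.3, 40)
        c = fit_linear_risk_score(X, y, ElasticNetConfig(alpha=1.0, lam=0.2))
        dupes = [abs(c.coefficients["a"]) > 1e-8, abs(c.coefficients["a_copy"]) > 1e-8]
        assert sum(dupes) <= 1

    def test_degenerate_inputs_rejected(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        with pytest.raises(ValidationError):
            fit_linear_risk_score(X, pd.Series(np.ones(20)), ElasticNetConfig())
        with pytest.raises(ProtocolError):
            fit_linear_risk_score(X.head(5), pd.Series(np.arange(5.0)), ElasticNetConfig())

    def test_missing_rows_excluded(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        X.loc[0, "a"] = np.nan
        y = X["b"].fillna(0) * 2 + rng.normal(0, 0.1, 30)
        c = fit_linear_risk_score(X, y, ElasticNetConfig(alpha=1.0, lam=0.05))
        assert np.isfinite(list(c.coefficients.values())).all()


class TestCutpoint:
    def test_separable_scores(self):
        cp = find_cutpoint(np.array([1, 2, 3, 10, 11.0]), np.array([0, 0, 0, 1, 1]))
        assert cp.youden == pytest.approx(1.0)
        assert 3 < cp.cutoff <= 10
        assert cp.direction == "ge"

    def test_null_scores_have_small_youden(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, 200)
        cp = find_cutpoint(scores, labels)
        assert cp.youden <= 0.25

    def test_reversed_labels_flip_direction(self):
        scores = np.array([1, 2, 3, 10, 11.0])
        fwd = find_cutpoint(scores, np.array([0, 0, 0, 1, 1]))
        rev = find_cutpoint(scores, np.array([1, 1, 1, 0, 0]))
        assert fwd.youden == pytest.approx(rev.youden)
        assert rev.direction == "le"

    def test_single_class_rejected(self):
        with pytest.raises(ProtocolError):
            find_cutpoint(np.arange(5.0), np.ones(5))


class TestSmote:
    def test_balances_exactly(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 4))
        y = np.array([1] * 6 + [0] * 34)
        Xb, yb = smote_oversample(X, y, seed=3)
        counts = np.bincount(yb)
        assert counts[0] == counts[1] == 34
        # originals preserved verbatim
        np.testing.assert_array_equal(Xb[:40], X)

    def test_synthetic_samples_interpolate_minority(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(10, 0.1, size=(5, 2)), rng.normal(-10, 0.1, size=(20, 2))])
        y = np.array([1] * 5 + [0] * 20)
        Xb, yb = smote_oversample(X, y, seed=0)
        synth = Xb[25:]
        assert (synth > 5).all()  # interpolants stay inside the minority cloud

    def test_depends_only_on_training_content(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 3))
        y = np.array([1] * 5 + [0] * 25)
        a = smote_oversample(X, y, seed=9)[0]
        b = smote_oversample(X, y, seed=9)[0]
        np.testing.assert_array_equal(a, b)  # no hidden global state


class TestClassifierProtocol:
    def test_training_folds_balanced_and_disjoint_from_test(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(45, 4)))
        y = np.array([1] * 10 + [0] * 35)
        rep = train_platinum_classifier(X, y, ClassifierProtocol(repeats=3, seed=0))
        assert rep.fold_details
        for fd in rep.fold_details:
            counts = fd["balanced_counts"]
            assert counts[0] == counts[1]
            assert set(fd["train_index"]).isdisjoint(fd["test_index"])

    def test_small_class_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 2)))
        with pytest.raises(ProtocolError):
            train_platinum_classifier(X, np.array([1] + [0] * 9), ClassifierProtocol())

    def test_rfe_selects_from_grid(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(60, 30)), columns=[f"f{i}" for i in range(30)])
        y = np.array([1] * 14 + [0] * 46)
        rng.shuffle(y)
        X["f0"] += 3 * y
        rep = train_platinum_classifier(
            X, y, ClassifierProtocol(repeats=3, use_rfe=True, seed=0)
        )
        assert set(rep.n_features_selected) <= {5, 10, 15, 20, 25}
        assert rep.auroc > 0.8

    def test_importances_scaled_to_100(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = np.array([1] * 12 + [0] * 28)
        X["a"] += 2 * y
        rep = train_platinum_classifier(X, y, ClassifierProtocol(repeats=10, seed=0))
        assert max(rep.importances.values()) == pytest.approx(100.0)
        assert max(rep.importances, key=rep.importances.get) == "a"

    def test_compare_requires_matching_repeats(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(30, 2)))
        y = np.array([1] * 8 + [0] * 22)
        a = train_platinum_classifier(X, y, ClassifierProtocol(repeats=5, seed=0))
        b = train_platinum_classifier(X, y, ClassifierProtocol(repeats=6, seed=0))
        with pytest.raises(ProtocolError):
            compare_classifiers(a, b)


class TestScreens:
    def test_null_features_mostly_robust(self):
        rng = np.random.default_rng(0)
        F = pd.DataFrame(rng.normal(size=(75, 40)), columns=[f"f{i}" for i in range(40)])
        scanner = np.array(["GE"] * 40 + ["nonGE"] * 35)
        screen = scanner_robustness_screen(F, scanner)
        assert screen["robust"].mean() >= 0.9

    def test_constant_feature_flagged(self):
        F = pd.DataFrame({"c": np.ones(20), "x": np.arange(20.0)})
        screen = scanner_robustness_screen(F, np.array(["GE"] * 10 + ["nonGE"] * 10))
        assert screen.loc["c", "p_value"] == 1.0 and screen.loc["c", "constant"]

    def test_single_group_rejected(self):
        F = pd.DataFrame({"x": np.arange(10.0)})
        with pytest.raises(ProtocolError):
            scanner_robustness_screen(F, np.array(["GE"] * 10))

    def test_monotone_pairs(self):
        idx = [f"p{i}" for i in range(12)]
        R = pd.DataFrame({"up": np.arange(12.0)}, index=idx)
        E = pd.DataFrame({"inc": np.arange(12.0) ** 2, "dec": -np.arange(12.0)}, index=idx)
        out = correlation_screen(R, E)
        assert out["rho"].loc["up", "inc"] == pytest.approx(1.0)
        assert out["rho"].loc["up", "dec"] == pytest.approx(-1.0)

    def test_tied_ranks_match_bruteforce(self):
        from scipy.stats import rankdata

        x = np.array([1, 2, 2, 3, 3, 3, 4, 5, 5, 6.0])
        y = np.array([2, 1, 3, 3, 5, 4, 4, 7, 6, 6.0])
        idx = [f"p{i}" for i in range(10)]
        out = correlation_screen(
            pd.DataFrame({"x": x}, index=idx), pd.DataFrame({"y": y}, index=idx)
        )
        rx, ry = rankdata(x), rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]  # tie-corrected rank formula
        assert out["rho"].loc["x", "y"] == pytest.approx(expected, abs=1e-12)

    def test_too_few_pairs_not_evaluable(self):
        idx = [f"p{i}" for i in range(4)]
        out = correlation_screen(
            pd.DataFrame({"x": np.arange(4.0)}, index=idx),
            pd.DataFrame({"y": np.arange(4.0)}, index=idx),
        )
        assert not out["evaluable"].loc["x", "y"]
        assert np.isnan(out["rho"].loc["x", "y"])


class TestSurvival:
    def test_null_score_ci_covers_one(self):
        covered = 0
        for s in range(25):
            rng = np.random.default_rng(s)
            score = rng.normal(size=200)
            t = rng.exponential(10, size=200)
            res = survival_association(score, t, np.ones(200))
            lo, hi = res["hr_ci"]
            covered += lo <= 1.0 <= hi
        assert covered >= 22  # >= 90% coverage under the null

    def test_log_hazard_recovery(self):
        rng = np.random.default_rng(1)
        score = rng.normal(0, 10, size=500)
        lam = 0.05 * np.exp(0.03 * score)
        t = rng.exponential(1 / lam)
        res = survival_association(score, t, np.ones(500))
        assert res["log_hr"] == pytest.approx(0.03, rel=0.3)

    def test_constant_score_rejected(self):
        with pytest.raises(ValidationError):
            survival_association(np.ones(20), np.arange(1, 21.0), np.ones(20))
        with pytest.raises(ValidationError):
            survival_association(np.arange(20.0), np.arange(1, 21.0), np.zeros(20))

    def test_km_groups_and_logrank(self):
        rng = np.random.default_rng(1)
        t = np.concatenate([rng.exponential(5, 100), rng.exponential(20, 100)])
        group = np.array([0] * 100 + [1] * 100)
        out = kaplan_meier_by_group(t, np.ones(200), group)
        assert out["groups"]["0"]["median_survival"] < out["groups"]["1"]["median_survival"]
        assert out["logrank_p"] < 1e-6
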