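"""Logistic diagnostic models, collinearity/calibration diagnostics, ROC."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

import autonomics as au


def logistic_data(n, beta, rng, n_null=2):
    """Binary outcome driven by one true predictor plus null candidates."""
    x = rng.normal(size=(n, 1 + n_null))
    eta = 0.2 + beta * x[:, 0]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    cols = {"y": y, "x_true": x[:, 0]}
    cols.update({f"x_null{i}": x[:, i + 1] for i in range(n_null)})
    return pd.DataFrame(cols)


class TestPredictProbability:
    def test_null_model_gives_half(self):
        m = au.DiagnosticModel(predictors={"a": 0.0}, constant=0.0)
        assert au.predict_probability(m, {"a": 123.0}) == pytest.approx(0.5)

    def test_published_model_one_at_origin(self):
        p = au.predict_probability(au.PUBLISHED_MODEL_1,
                                   {"TP_HRV_SR": 0.0, "TP_RV_SR": 0.0})
        assert p == pytest.approx(1.0 / (1.0 + math.exp(-0.504)))

    def test_high_hrv_power_drives_probability_to_zero(self):
        p = au.predict_probability(au.PUBLISHED_MODEL_1,
                                   {"TP_HRV_SR": 1e5, "TP_RV_SR": 0.0})
        assert p < 1e-10

    def test_missing_predictor_rejected(self):
        with pytest.raises(KeyError, match="TP_RV_SR"):
            au.predict_probability(au.PUBLISHED_MODEL_1, {"TP_HRV_SR": 0.0})

    def test_monotone_in_each_predictor_per_sign(self):
        m = au.PUBLISHED_MODEL_2
        base = {k: 100.0 for k in m.predictors}
        p0 = au.predict_probability(m, base)
        for name, b in m.predictors.items():
            up = dict(base, **{name: 200.0})
            if b > 0:
                assert au.predict_probability(m, up) > p0
            else:
                assert au.predict_probability(m, up) < p0


class TestStepwise:
    def test_forward_recovers_true_predictor(self):
        data = logistic_data(300, 1.5, np.random.default_rng(0))
        m = au.fit_stepwise_logistic(data, "y", ["x_true", "x_null0", "x_null1"],
                                     method="forward")
        assert "x_true" in m.predictors
        assert m.predictors["x_true"] == pytest.approx(1.5, rel=0.35)

    def test_all_null_candidates_give_intercept_only(self):
        sig = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            data = logistic_data(200, 0.0, rng)
            m = au.fit_stepwise_logistic(
                data, "y", ["x_true", "x_null0", "x_null1"], method="forward")
            sig += len(m.predictors)
        # selection at p<0.05 admits a null occasionally, but rarely
        assert sig <= 2

    def test_forward_and_backward_agree_on_strong_predictor(self):
        data = logistic_data(400, 2.0, np.random.default_rng(1))
        mf = au.fit_stepwise_logistic(data, "y", ["x_true", "x_null0", "x_null1"],
                                      method="forward")
        mb = au.fit_stepwise_logistic(data, "y", ["x_true", "x_null0", "x_null1"],
                                      method="backward", remove_p=0.05)
        assert set(mf.predictors) == set(mb.predictors) == {"x_true"}
        assert mf.predictors["x_true"] == pytest.approx(mb.predictors["x_true"],
                                                        rel=1e-6)

    def test_separation_flagged(self):
        x = np.linspace(-2, 2, 40)
        data = pd.DataFrame({"y": (x > 0).astype(float), "x_true": x,
                             "a": np.random.default_rng(2).normal(size=40)})
        m = au.fit_stepwise_logistic(data, "y", ["x_true", "a"], method="forward")
        assert m.separation

    def test_nonbinary_outcome_rejected(self):
        data = pd.DataFrame({"y": [0.0, 1.0, 2.0] * 10, "x": np.arange(30.0)})
        with pytest.raises(ValueError, match="binary"):
            au.fit_stepwise_logistic(data, "y", ["x"])


class TestVif:
    def test_orthogonal_predictors_unit_vif(self):
        rng = np.random.default_rng(3)
        q, _ = np.linalg.qr(rng.normal(size=(50, 3)))
        q = q - q.mean(axis=0)  # keep centered orthogonality approximate
        design = pd.DataFrame(np.linalg.qr(q)[0], columns=list("abc"))
        out = au.vif(design)
        for v in out.values():
            assert v == pytest.approx(1.0, abs=0.05)

    def test_duplicated_predictor_infinite(self):
        x = np.random.default_rng(4).normal(size=30)
        out = au.vif(pd.DataFrame({"a": x, "b": x, "c": np.arange(30.0)}))
        assert math.isinf(out["a"]) and math.isinf(out["b"])

    def test_known_r_squared_gives_closed_form_vif(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=200)
        e = rng.normal(size=200)
        # orthogonalize and standardize so the sample R^2 is exactly 0.75
        x = (x - x.mean()) / x.std()
        e = e - e.mean() - x * (e @ x) / (x @ x) * 1.0
        e = e / np.sqrt(e @ e) * np.sqrt(x @ x)
        x2 = math.sqrt(0.75) * x + math.sqrt(0.25) * e
        out = au.vif(pd.DataFrame({"a": x, "b": x2}))
        assert out["a"] == pytest.approx(4.0, rel=1e-6)
        assert out["b"] == pytest.approx(4.0, rel=1e-6)


class TestHosmerLemeshow:
    def test_two_groups_refused(self):
        with pytest.raises(ValueError, match="n_groups"):
            au.hosmer_lemeshow(np.linspace(0.1, 0.9, 50), np.zeros(50), n_groups=2)

    def test_calibrated_model_gives_uniform_p(self):
        # simulate from a logistic model, refit, test the fitted risks:
        # under correct calibration the p-values are roughly uniform
        import statsmodels.api as sm
        rng = np.random.default_rng(6)
        pvals = []
        for _ in range(100):
            x = rng.normal(size=300)
            y = (rng.random(300) < 1 / (1 + np.exp(-(0.2 + x)))).astype(float)
            fit = sm.GLM(y, sm.add_constant(x),
                         family=sm.families.Binomial()).fit()
            _, pv = au.hosmer_lemeshow(fit.fittedvalues, y)
            pvals.append(pv)
        _, ks_p = sst.kstest(pvals, "uniform")
        assert ks_p > 0.01

    def test_miscalibration_detected(self):
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(20):
            p = rng.uniform(0.05, 0.95, size=500)
            y = (rng.random(500) < p**2).astype(float)  # systematically off
            _, pv = au.hosmer_lemeshow(p, y)
            rejections += pv < 0.05
        assert rejections >= 18


class TestRoc:
    def test_perfect_separation(self):
        r = au.roc_cutoffs(np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0]),
                           np.array([0, 0, 0, 1, 1, 1]))
        assert r.auc == 1.0
        assert r.se_youden == 1.0 and r.sp_youden == 1.0
        assert 3.0 < r.cutoff_youden < 10.0

    def test_identical_scores_auc_half(self):
        r = au.roc_cutoffs(np.full(10, 5.0), np.array([0, 1] * 5))
        assert r.auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            au.roc_cutoffs(np.arange(5.0), np.ones(5, dtype=int))

    def test_orientation_auto_detected(self):
        scores = np.array([10.0, 9.0, 8.0, 1.0, 2.0, 3.0])
        labels = np.array([0, 0, 0, 1, 1, 1])  # low score marks a case
        r = au.roc_cutoffs(scores, labels)
        assert r.auc == 1.0 and r.orientation == "lower"

    def test_auc_matches_concordant_pair_counting(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            n = int(rng.integers(4, 13))
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            scores = rng.integers(0, 5, size=n).astype(float)  # ties likely
            pos, neg = scores[labels == 1], scores[labels == 0]
            brute = sum(1.0 if a > b else 0.5 if a == b else 0.0
                        for a in pos for b in neg) / (len(pos) * len(neg))
            r = au.roc_cutoffs(scores, labels)
            oriented = brute if brute >= 0.5 else 1.0 - brute
            assert r.auc == pytest.approx(oriented)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=40)
        labels = (rng.random(40) < 0.5).astype(int)
        labels[0], labels[1] = 0, 1
        a = au.roc_cutoffs(scores, labels).auc
        b = au.roc_cutoffs(np.exp(3 * scores), labels).auc
        assert a == pytest.approx(b)

    def test_balanced_cutoff_minimises_se_sp_gap(self):
        rng = np.random.default_rng(10)
        scores = np.concatenate([rng.normal(0, 1, 50), rng.normal(1.5, 1, 50)])
        labels = np.concatenate([np.zeros(50, int), np.ones(50, int)])
        r = au.roc_cutoffs(scores, labels)
        assert abs(r.se_balanced - r.sp_balanced) <= abs(r.se_youden - r.sp_youden) + 1e-12

    def test_simulated_cohort_single_feature_auc(self, small_cohort_spectra):
        """TP of HRV at rest separates simulated ME/CFS from controls with
        AUC comparable to the reported 0.82."""
        sub = small_cohort_spectra
        sub = sub[(sub.signal == "RR") & (sub.protocol == "SR") &
                  (sub.group.isin(["HC", "MECFS"]))]
        r = au.roc_cutoffs(sub["tp"].to_numpy(),
                           (sub.group == "MECFS").astype(int).to_numpy())
        assert r.auc > 0.7
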