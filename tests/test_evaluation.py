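import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from adnexrad.evaluation import (auc, calibration, decision_curve,
                                 delong_compare, delong_variance,
                                 manufacturer_pca, metrics_at_cutoff,
                                 shap_overfit_table, shap_values,
                                 youden_cutoff, _rank_auc)
from adnexrad.modeling import tune_and_train

TOY_RISKS = np.array([0.1, 0.4, 0.35, 0.8])
TOY_LABELS = np.array([0, 0, 1, 1])


class TestAUC:
    def test_concordance_hand_example(self):
        point, _ = auc(TOY_RISKS, TOY_LABELS, n_boot=100)
        assert point == pytest.approx(0.75, abs=1e-12)

    def test_label_flip_complements(self, rng):
        r = rng.uniform(size=60)
        y = rng.integers(0, 2, size=60)
        y[:2] = [0, 1]
        a1, _ = auc(r, y, n_boot=50)
        a2, _ = auc(r, 1 - y, n_boot=50)
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_perfect_separation(self):
        point, ci = auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], n_boot=200)
        assert point == 1.0 and ci[1] == 1.0

    def test_equals_mannwhitney_u_identity_and_sklearn(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 80))
            r = rng.normal(size=n)
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            r[rng.integers(0, n)] = r[0]  # inject ties
            from scipy.stats import mannwhitneyu
            u = mannwhitneyu(r[y == 1], r[y == 0]).statistic
            expected = u / ((y == 1).sum() * (y == 0).sum())
            assert _rank_auc(r, y) == pytest.approx(expected, abs=1e-12)
            assert _rank_auc(r, y) == pytest.approx(roc_auc_score(y, r), abs=1e-12)

    def test_bootstrap_ci_brackets_point_and_is_seeded(self, rng):
        r = rng.uniform(size=200)
        y = (r + 0.3 * rng.normal(size=200) > 0.5).astype(int)
        p1, ci1 = auc(r, y, seed=4)
        p2, ci2 = auc(r, y, seed=4)
        assert ci1 == ci2
        assert ci1[0] <= p1 <= ci1[1]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])


class TestDeLong:
    def test_identical_models_give_p_one(self):
        p, z = delong_compare(TOY_RISKS, TOY_RISKS, TOY_LABELS)
        assert p == 1.0 and z == 0.0

    def test_symmetry_under_model_swap(self, rng):
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        a = rng.uniform(size=50)
        b = rng.uniform(size=50)
        p1, z1 = delong_compare(a, b, y)
        p2, z2 = delong_compare(b, a, y)
        assert p1 == pytest.approx(p2, abs=1e-14)
        assert z1 == pytest.approx(-z2, abs=1e-14)

    def test_variance_matches_grouped_jackknife_oracle_at_n8(self, rng):
        """DeLong's structural-component variance equals the delete-one
        (grouped jackknife) recomputation exactly."""
        for _ in range(10):
            y = np.array([1, 1, 1, 0, 0, 0, 0, 1])
            r = rng.normal(size=8)
            v = delong_variance(r, y)
            pos = np.flatnonzero(y == 1)
            neg = np.flatnonzero(y == 0)
            parts = []
            for group in (pos, neg):
                thetas = []
                for i in group:
                    keep = np.ones(8, bool)
                    keep[i] = False
                    thetas.append(_rank_auc(r[keep], y[keep]))
                thetas = np.array(thetas)
                g = len(group)
                parts.append((g - 1) / g * np.sum((thetas - thetas.mean()) ** 2))
            assert v == pytest.approx(sum(parts), abs=1e-10)

    def test_unpaired_inputs_rejected(self):
        with pytest.raises(ValueError):
            delong_compare([0.1, 0.2], [0.1, 0.2, 0.3], [0, 1, 1])


class TestMetricsAtCutoff:
    def test_confusion_hand_example(self):
        m = metrics_at_cutoff([0.2, 0.05, 0.9, 0.6], [0, 0, 1, 1], cutoff=0.10)
        assert m.sensitivity == 1.0 and m.specificity == 0.5

    def test_all_below_cutoff(self):
        m = metrics_at_cutoff([0.01, 0.02, 0.03, 0.04], [0, 0, 1, 1], cutoff=0.5)
        assert m.sensitivity == 0.0 and m.specificity == 1.0

    def test_lr_identity_and_ci_presence(self, rng):
        r = rng.uniform(size=300)
        y = (r + 0.4 * rng.normal(size=300) > 0.5).astype(int)
        m = metrics_at_cutoff(r, y, cutoff=0.10)
        assert m.lr_pos == pytest.approx(m.sensitivity / (1 - m.specificity))
        lo, hi = m.ci["sensitivity"]
        assert lo <= m.sensitivity <= hi
        assert m.ci["lr_pos"][0] <= m.lr_pos <= m.ci["lr_pos"][1]

    def test_normal_approximation_ci_halfwidth(self):
        m = metrics_at_cutoff([0.2, 0.2, 0.9, 0.9, 0.9, 0.05], [0, 0, 1, 1, 1, 0],
                              cutoff=0.5)
        p, n = 1.0, 3
        lo, hi = m.ci["sensitivity"]
        assert hi == 1.0 and lo == pytest.approx(max(0, p - 1.96 * 0), abs=1e-12)

    def test_cutoff_sweep_reconstructs_youden(self, rng):
        r = rng.uniform(0.01, 0.99, size=120)
        y = (r + 0.3 * rng.normal(size=120) > 0.5).astype(int)
        c, j = youden_cutoff(r, y)
        js = []
        for t in np.unique(r):
            m = metrics_at_cutoff(r, y, float(np.clip(t, 1e-6, 1 - 1e-6)))
            js.append(m.sensitivity + m.specificity - 1)
        assert j == pytest.approx(max(js), abs=1e-12)


class TestYouden:
    def test_toy_optimum_with_tie_toward_low_cutoff(self):
        c, j = youden_cutoff(TOY_RISKS, TOY_LABELS)
        assert j == pytest.approx(0.5, abs=1e-12)
        assert c == pytest.approx(0.35, abs=1e-12)

    def test_perfect_separation_gives_j_one(self):
        c, j = youden_cutoff([0.1, 0.2, 0.7, 0.9], [0, 0, 1, 1])
        assert j == 1.0


class TestCalibration:
    def test_self_consistent_risks_recover_identity(self, rng):
        r = rng.uniform(0.02, 0.98, size=10_000)
        y = rng.binomial(1, r)
        cal = calibration(r, y)
        assert abs(cal.intercept) < 0.1
        assert abs(cal.slope - 1.0) < 0.05

    def test_halved_odds_flagged_as_underestimation(self, rng):
        r = rng.uniform(0.05, 0.9, size=5000)
        y = rng.binomial(1, r)
        odds = r / (1 - r) / 2.0
        r_under = odds / (1 + odds)
        cal = calibration(r_under, y)
        assert cal.intercept > 0  # risks systematically underestimated

    def test_known_affine_logit_distortion_recovered(self, rng):
        a, b = -0.4, 1.6
        lp = rng.normal(-0.5, 1.2, size=20_000)
        y = rng.binomial(1, 1 / (1 + np.exp(-lp)))
        distorted = 1 / (1 + np.exp(-(lp - a) / b))  # so a + b*logit(r) = lp
        cal = calibration(distorted, y)
        assert cal.intercept == pytest.approx(a, abs=0.1)
        assert cal.slope == pytest.approx(b, abs=0.1)

    def test_constant_risks_rejected(self):
        with pytest.raises(ValueError):
            calibration([0.3, 0.3, 0.3, 0.3], [0, 1, 0, 1])

    def test_curve_spans_risk_range(self, rng):
        r = rng.uniform(0.1, 0.9, size=2000)
        y = rng.binomial(1, r)
        cal = calibration(r, y)
        assert cal.curve["predicted"].iloc[0] == pytest.approx(r.min())
        assert cal.curve["predicted"].iloc[-1] == pytest.approx(r.max())
        mid = cal.curve.dropna()
        assert ((mid["observed"] > -0.2) & (mid["observed"] < 1.2)).all()


class TestDecisionCurve:
    def test_treat_all_closed_form_every_grid_point(self, rng):
        y = np.array([1] * 40 + [0] * 60)
        dc = decision_curve({}, y)
        pi = 0.4
        expected = pi - (1 - pi) * dc["threshold"] / (1 - dc["threshold"])
        np.testing.assert_allclose(dc["treat_all"], expected, atol=1e-12)
        assert dc.loc[np.isclose(dc["threshold"], 0.10), "treat_all"].iloc[0] \
            == pytest.approx(0.4 - 0.6 / 9, abs=1e-12)

    def test_treat_none_identically_zero(self):
        dc = decision_curve({}, [0, 1, 1, 0])
        assert (dc["treat_none"] == 0).all()

    def test_perfect_classifier_net_benefit_equals_prevalence(self):
        y = np.array([0] * 30 + [1] * 20)
        r = y.astype(float)
        dc = decision_curve({"perfect": r}, y)
        np.testing.assert_allclose(dc["perfect"], 0.4, atol=1e-12)

    def test_threshold_grid_bounds_validated(self):
        with pytest.raises(ValueError):
            decision_curve({}, [0, 1], grid=np.array([0.0, 0.5]))


@pytest.fixture(scope="module")
def overfit_setup():
    rng = np.random.default_rng(8)
    n = 200
    y = rng.integers(0, 2, size=n)
    X = pd.DataFrame({"signal": y + 0.6 * rng.normal(size=n),
                      "noise": rng.normal(size=n)})
    model = tune_and_train("gradient_boosted_trees", X, y, n_search=3, seed=0)
    return model, X, y


class TestShapOverfit:
    def test_additivity_of_attributions(self, overfit_setup):
        model, X, _ = overfit_setup
        contrib = shap_values(model, X)
        risks = model.predict_risk(X)
        margins = np.log(np.clip(risks, 1e-12, 1) / np.clip(1 - risks, 1e-12, 1))
        np.testing.assert_allclose(contrib.sum(axis=1), margins, atol=1e-4)

    def test_identical_splits_give_zero_scores(self, overfit_setup):
        model, X, _ = overfit_setup
        tab = shap_overfit_table(model, X, X)
        assert np.allclose(tab["overfit_score"], 0.0)

    def test_non_tree_model_rejected(self):
        X = pd.DataFrame({"a": [0.0, 1.0] * 10})
        y = [0, 1] * 10
        lr = tune_and_train("penalized_logistic", X, y, n_search=2, seed=0)
        with pytest.raises(ValueError):
            shap_overfit_table(lr, X, X)

    def test_memorized_train_artifact_tops_the_table(self):
        """A feature correlated with the outcome only in the training split
        (a leak) must receive the top Overfit_Score."""
        rng = np.random.default_rng(0)
        n = 150
        y_tr = rng.integers(0, 2, size=n)
        y_va = rng.integers(0, 2, size=n)
        X_tr = pd.DataFrame({"honest": y_tr + 1.0 * rng.normal(size=n),
                             "leak": y_tr + 0.3 * rng.normal(size=n)})
        X_va = pd.DataFrame({"honest": y_va + 1.0 * rng.normal(size=n),
                             "leak": rng.normal(loc=0.5, scale=0.15, size=n)})
        model = tune_and_train("gradient_boosted_trees", X_tr, y_tr,
                               n_search=3, seed=0)
        tab = shap_overfit_table(model, X_tr, X_va)
        assert tab["feature"].iloc[0] == "leak"


class TestManufacturerPCA:
    def test_exchangeable_tags_overlap(self, rng):
        X = pd.DataFrame(rng.normal(size=(300, 6)))
        tags = rng.choice(["a", "b", "c"], size=300)
        scores, summary = manufacturer_pca(X, tags)
        assert summary["overlap_ratio"] < 1.0

    def test_explained_variance_non_increasing(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 5)))
        _, summary = manufacturer_pca(X, rng.choice(["a", "b"], size=100))
        ev = summary["explained_variance_ratio"]
        assert all(ev[i] >= ev[i + 1] for i in range(len(ev) - 1))

    def test_single_tag_warns(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 4)))
        with pytest.warns(UserWarning):
            _, summary = manufacturer_pca(X, np.array(["only"] * 50))
        assert summary["overlap_ratio"] == 0.0

    def test_gain_offset_effect_removed_by_zscoring(self, small_features,
                                                    small_clinical):
        """The generator's vendor gain/offset is removed by per-ROI
        normalization, so vendor clusters must overlap in feature space."""
        _, summary = manufacturer_pca(small_features,
                                      small_clinical["manufacturer"].to_numpy())
        assert summary["overlap_ratio"] < 1.0
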