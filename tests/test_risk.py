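"""Risk labeling, LASSO-Cox gating, balanced patient-disjoint CV, baseline."""

import numpy as np
import pandas as pd
import pytest

import morphocensus as mc

DAYS = 365.25


def _clinical(rows):
    df = pd.DataFrame(rows)
    df["patient_id"] = [f"P{i}" for i in range(len(df))]
    return df


class TestAssignRiskLabels:
    def test_survival_endpoint_rules(self):
        cl = _clinical([
            dict(surv_time_days=3 * DAYS, death_event=1,
                 met_time_days=3 * DAYS, met_event=0),   # death at 3y -> high
            dict(surv_time_days=4 * DAYS, death_event=0,
                 met_time_days=4 * DAYS, met_event=0),   # censored 4y -> excluded
            dict(surv_time_days=6 * DAYS, death_event=0,
                 met_time_days=6 * DAYS, met_event=0),   # alive 6y -> low
            dict(surv_time_days=7 * DAYS, death_event=1,
                 met_time_days=7 * DAYS, met_event=0),   # death after 5y -> low
        ])
        lab = mc.assign_risk_labels(cl, "survival")
        assert lab.label.tolist() == ["high", "excluded", "low", "low"]

    def test_metastasis_any_time_is_high(self):
        cl = _clinical([
            dict(surv_time_days=7 * DAYS, death_event=0,
                 met_time_days=7 * DAYS, met_event=1),   # met at 7y
        ])
        assert mc.assign_risk_labels(cl, "metastasis").label.tolist() == ["high"]
        # same follow-up, survival endpoint: event-free 7y -> low
        assert mc.assign_risk_labels(cl, "survival").label.tolist() == ["low"]

    def test_metastasis_censored_before_horizon_excluded(self):
        cl = _clinical([
            dict(surv_time_days=2 * DAYS, death_event=0,
                 met_time_days=2 * DAYS, met_event=0),
        ])
        assert mc.assign_risk_labels(cl, "metastasis").label.tolist() == ["excluded"]

    def test_negative_times_rejected(self):
        cl = _clinical([dict(surv_time_days=-1, death_event=0,
                             met_time_days=1, met_event=0)])
        with pytest.raises(ValueError):
            mc.assign_risk_labels(cl, "survival")


class TestLassoCoxPath:
    def test_largest_penalty_selects_nothing(self):
        X, t, e = mc.simulate_feature_cohort(150, hazard_ratio=2.0, seed=0)
        sel = mc.lasso_cox_path(X, t, e, seed=0)
        first = sel.coef_path.iloc[:, 0]  # largest alpha on the path
        assert (first == 0).all()

    def test_planted_feature_recovered_with_positive_sign(self):
        for seed in range(5):
            X, t, e = mc.simulate_feature_cohort(300, n_noise=10,
                                                 hazard_ratio=3.0, seed=seed)
            sel = mc.lasso_cox_path(X, t, e, seed=seed)
            assert "planted" in sel.features_min
            assert sel.coefficients.loc["planted", "min"] > 0

    def test_one_se_at_least_min_and_concordance_max(self):
        for seed in (1, 2, 3):
            X, t, e = mc.simulate_feature_cohort(120, hazard_ratio=2.5,
                                                 seed=seed)
            sel = mc.lasso_cox_path(X, t, e, seed=seed)
            assert sel.alpha_1se >= sel.alpha_min
            i_min = int(np.argmin(np.abs(sel.alphas - sel.alpha_min)))
            assert sel.cv_concordance_mean[i_min] == pytest.approx(
                np.nanmax(sel.cv_concordance_mean))
            assert set(sel.features_1se) <= set(X.columns)

    def test_no_events_rejected(self):
        X, t, _ = mc.simulate_feature_cohort(50, seed=0)
        with pytest.raises(ValueError):
            mc.lasso_cox_path(X, t, np.zeros(50, int))


class TestPatientFolds:
    def test_ten_patients_five_folds_of_two(self):
        ids = [f"P{i}" for i in range(10)]
        folds = mc.patient_folds(ids, k=5, seed=0)
        sizes = pd.Series(folds).value_counts()
        assert sorted(sizes) == [2, 2, 2, 2, 2]

    def test_partition_property(self):
        ids = [f"P{i}" for i in range(23)]
        folds = mc.patient_folds(ids, k=5, seed=3)
        assert set(folds) == set(ids)
        sizes = pd.Series(folds).value_counts()
        assert sizes.max() - sizes.min() <= 1

    def test_different_seeds_differ(self):
        ids = [f"P{i}" for i in range(30)]
        assert mc.patient_folds(ids, seed=1) != mc.patient_folds(ids, seed=2)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            mc.patient_folds(["a", "b", "c"], k=1)


class TestBalanceUpsample:
    def test_minority_upsampled_to_majority(self):
        labels = np.array(["high"] * 30 + ["low"] * 10)
        idx = mc.balance_upsample(labels, seed=0)
        resampled = labels[idx]
        assert (resampled == "high").sum() == 30
        assert (resampled == "low").sum() == 30
        assert set(np.arange(40)) <= set(idx)  # originals all present

    def test_balanced_input_unchanged(self):
        labels = np.array(["high"] * 5 + ["low"] * 5)
        assert len(mc.balance_upsample(labels, seed=0)) == 10

    def test_deterministic(self):
        labels = np.array(["high"] * 9 + ["low"] * 4)
        a = mc.balance_upsample(labels, seed=7)
        b = mc.balance_upsample(labels, seed=7)
        assert np.array_equal(a, b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            mc.balance_upsample(np.array(["high"] * 5), seed=0)


def _separable_cohort(n=60, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"P{i}" for i in range(n)]
    y = np.array(["high" if i < n // 2 else "low" for i in range(n)])
    X = pd.DataFrame({
        "signal": np.where(y == "high", 3.0, -3.0) + 0.3 * rng.standard_normal(n),
        "noise": rng.standard_normal(n),
    }, index=ids)
    return X, pd.Series(y, index=ids)


class TestEvaluateClassifiers:
    def test_separable_cohort_logistic_near_perfect(self):
        X, y = _separable_cohort()
        folds = mc.patient_folds(list(X.index), seed=0)
        res = mc.evaluate_classifiers(X, y, folds, seed=0)
        assert set(res) == set(mc.MODEL_KINDS)
        assert res["logistic"].f1 >= 0.95

    def test_every_patient_predicted_exactly_once(self):
        X, y = _separable_cohort(seed=1)
        folds = mc.patient_folds(list(X.index), seed=1)
        res = mc.evaluate_classifiers(X, y, folds, model_kinds=("knn",), seed=1)
        preds = res["knn"].predictions
        assert sorted(preds.patient_id) == sorted(X.index)

    def test_logistic_coefficients_per_fold(self):
        X, y = _separable_cohort(seed=2)
        folds = mc.patient_folds(list(X.index), seed=2)
        res = mc.evaluate_classifiers(X, y, folds, model_kinds=("logistic",),
                                      seed=2)
        coefs = res["logistic"].coefficients
        assert coefs.shape == (5, 2)
        assert (coefs["signal"] > 0).all()  # high-risk direction

    def test_selected_feature_restriction(self):
        X, y = _separable_cohort(seed=3)
        folds = mc.patient_folds(list(X.index), seed=3)
        res = mc.evaluate_classifiers(X, y, folds, model_kinds=("logistic",),
                                      seed=3, selected_features=["signal"])
        assert list(res["logistic"].coefficients.columns) == ["signal"]

    def test_single_class_fold_rejected(self):
        X, y = _separable_cohort(n=10, seed=4)
        folds = {pid: (0 if y[pid] == "high" else 1) for pid in X.index}
        with pytest.raises(ValueError):
            mc.evaluate_classifiers(X, y, folds, model_kinds=("logistic",))

    def test_deterministic_given_seed(self):
        X, y = _separable_cohort(seed=5)
        folds = mc.patient_folds(list(X.index), seed=5)
        a = mc.evaluate_classifiers(X, y, folds, model_kinds=("random_forest",),
                                    seed=5)["random_forest"]
        b = mc.evaluate_classifiers(X, y, folds, model_kinds=("random_forest",),
                                    seed=5)["random_forest"]
        assert a.predictions.equals(b.predictions)


class TestStageBaseline:
    def test_hand_confusion_matrix(self):
        # TP=5, FN=6, FP=4, TN=15
        rows, labels = [], []
        for stage, label, n in [("III", "high", 5), ("I", "high", 3),
                                ("II", "high", 3), ("III", "low", 4),
                                ("I", "low", 8), ("II", "low", 7)]:
            for _ in range(n):
                rows.append(stage)
                labels.append(label)
        clinical = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(len(rows))],
            "stage": rows,
        })
        lab = pd.DataFrame({
            "patient_id": clinical.patient_id,
            "endpoint": "survival",
            "label": labels,
        })
        res = mc.stage_baseline(clinical, lab)
        assert res.sensitivity == pytest.approx(5 / 11)
        assert res.specificity == pytest.approx(15 / 19)
        assert res.f1 == pytest.approx(0.5)

    def test_all_stage_three_all_high(self):
        clinical = pd.DataFrame({"patient_id": ["a", "b"], "stage": "III"})
        lab = pd.DataFrame({"patient_id": ["a", "b"], "endpoint": "survival",
                            "label": "high"})
        assert mc.stage_baseline(clinical, lab).sensitivity == 1.0

    def test_missing_stage_lists_patients(self):
        clinical = pd.DataFrame({"patient_id": ["a"], "stage": ["III"]})
        lab = pd.DataFrame({"patient_id": ["a", "b"], "endpoint": "survival",
                            "label": ["high", "low"]})
        with pytest.raises(ValueError, match="b"):
            mc.stage_baseline(clinical, lab)


class TestSignHelpers:
    def test_strong_signs_filter_weak_features(self):
        coefs = pd.DataFrame({
            "strong_pos": [1.0, 1.1, 0.9, 1.0, 1.2],
            "weak": [0.1, -0.2, 0.05, -0.1, 0.15],
            "strong_neg": [-2.0, -1.8, -2.1, -2.2, -1.9],
        })
        signs = mc.strong_coefficient_signs(coefs)
        assert signs.to_dict() == {"strong_pos": 1.0, "strong_neg": -1.0}

    def test_sign_agreement_fraction(self):
        a = pd.Series({"x": 1.0, "y": -1.0, "z": 1.0})
        b = pd.Series({"x": 1.0, "y": 1.0, "w": -1.0})
        assert mc.sign_agreement(a, b) == pytest.approx(0.5)
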