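"""Splitting, training, evaluation metrics, ablations, SHAP axioms."""
import numpy as np
import pandas as pd
import pytest

from breathprint.config import ConfigurationError, ModelConfig
from breathprint.features import FeatureSpec
from breathprint.model import (BracClassifier, MajorityClassModel, evaluate,
                               explain_shap, paired_bootstrap_auc,
                               run_ablations, split_by_user, train_gbct)


def _toy_matrix(n_users=40, rows_per_user=30, seed=0, informative=True,
                imbalance=0.5):
    """Small synthetic feature matrix with a controllable signal column."""
    rng = np.random.default_rng(seed)
    rows = []
    for u in range(n_users):
        habit = rng.normal()
        for _ in range(rows_per_user):
            signal = habit + rng.normal(0, 0.8)
            label = int((signal if informative else rng.normal())
                        > np.quantile(rng.normal(size=200), 1 - imbalance))
            rows.append({"user_id": f"u{u:03d}", "ts_utc": 0,
                         "sig": signal if informative else rng.normal(),
                         "noise1": rng.normal(), "noise2": rng.normal(),
                         "const": 1.0, "label_high": label})
    return pd.DataFrame(rows)


TOY_SPEC = FeatureSpec(features=["sig", "noise1", "noise2", "const"],
                       families={"sig": "prior_brac", "noise1": "temporal",
                                 "noise2": "temporal", "const": "estimate"})


class TestSplit:
    def test_counts_follow_largest_remainder(self):
        m = pd.DataFrame({"user_id": [f"u{i}" for i in range(10)]})
        split = split_by_user(m, (0.7, 0.1, 0.2), seed=3)
        counts = split.assignment.value_counts()
        assert counts["train"] == 7 and counts["validation"] == 1 \
            and counts["test"] == 2

    def test_all_records_of_user_share_split(self, small_matrix):
        split = split_by_user(small_matrix, seed=1)
        per_user = small_matrix["user_id"].map(split.assignment)
        assert per_user.groupby(small_matrix["user_id"]).nunique().eq(1).all()

    def test_deterministic_and_disjoint(self, small_matrix):
        a = split_by_user(small_matrix, seed=5).assignment
        b = split_by_user(small_matrix, seed=5).assignment
        pd.testing.assert_series_equal(a, b)
        assert set(a.unique()) == {"train", "validation", "test"}

    def test_bad_proportions_raise(self, small_matrix):
        with pytest.raises(ConfigurationError, match="sum to 1"):
            split_by_user(small_matrix, (0.5, 0.2, 0.2), seed=0)

    def test_too_few_users_raise(self):
        m = pd.DataFrame({"user_id": ["a", "b"]})
        with pytest.raises(ValueError, match="3 distinct users"):
            split_by_user(m)


class TestClassifier:
    def test_single_class_training_error_names_counts(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        with pytest.raises(ValueError, match="single class"):
            BracClassifier().fit(X, np.zeros(10))

    def test_fit_predict_shapes_and_params(self):
        m = _toy_matrix()
        clf = BracClassifier(n_estimators=20, seed=1)
        assert clf.get_params()["n_estimators"] == 20
        clf.fit(m[TOY_SPEC.features], m["label_high"])
        assert clf.n_features_in_ == 4
        p = clf.predict_proba(m[TOY_SPEC.features])
        assert p.shape == (len(m), 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0)

    def test_class_balancing_raises_sensitivity_under_imbalance(self):
        """With a 1:10 class ratio, inverse-frequency weighting must find
        more of the rare positive class at the 0.5 threshold."""
        m = _toy_matrix(n_users=60, seed=4, imbalance=0.09)
        split = split_by_user(m, seed=0)
        te = split.mask(m, "test")
        y = m["label_high"].to_numpy()
        reps = {}
        for bal in (True, False):
            cfg = ModelConfig(seed=1, class_balancing=bal)
            model = train_gbct(m, split, cfg, TOY_SPEC)
            reps[bal] = evaluate(model, m.loc[te, TOY_SPEC.features], y[te])
        assert reps[True].sensitivity > reps[False].sensitivity


class TestEvaluate:
    def test_perfectly_separable(self):
        class Perfect:
            def predict_proba(self, X):
                p = (np.asarray(X["sig"]) > 0).astype(float)
                return np.c_[1 - p, p]
        X = pd.DataFrame({"sig": np.r_[np.ones(30), -np.ones(70)]})
        y = np.r_[np.ones(30, int), np.zeros(70, int)]
        rep = evaluate(Perfect(), X, y)
        assert rep.roc_auc == 1.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_constant_scores_give_half_auc(self):
        class Constant:
            def predict_proba(self, X):
                return np.tile([0.6, 0.4], (len(X), 1))
        y = np.r_[np.ones(25, int), np.zeros(75, int)]
        rep = evaluate(Constant(), pd.DataFrame(index=range(100)), y)
        assert rep.roc_auc == 0.5

    def test_majority_class_row(self):
        """The constant majority predictor reproduces the degenerate
        baseline: AUC 0.50, sensitivity 0, specificity 1, precision
        undefined."""
        y_tr = np.r_[np.ones(30, int), np.zeros(70, int)]
        y_te = np.r_[np.ones(29, int), np.zeros(71, int)]
        model = MajorityClassModel().fit(None, y_tr)
        rep = evaluate(model, pd.DataFrame(index=range(100)), y_te)
        assert rep.roc_auc == 0.5
        assert rep.sensitivity == 0.0
        assert rep.specificity == 1.0
        assert rep.precision is None
        assert rep.to_dict()["precision"] == "Undefined"
        assert rep.accuracy == pytest.approx(0.71)

    def test_metrics_recomputable_from_confusion(self, small_matrix,
                                                 default_spec):
        split = split_by_user(small_matrix, seed=2)
        model = train_gbct(small_matrix, split, ModelConfig(seed=2),
                           default_spec)
        te = split.mask(small_matrix, "test")
        rep = evaluate(model, small_matrix.loc[te, default_spec.features],
                       small_matrix.loc[te, "label_high"])
        assert rep.n == rep.tn + rep.fp + rep.fn + rep.tp
        assert rep.sensitivity == pytest.approx(rep.tp / (rep.tp + rep.fn))
        assert rep.specificity == pytest.approx(rep.tn / (rep.tn + rep.fp))
        assert rep.accuracy == pytest.approx((rep.tp + rep.tn) / rep.n)

    def test_single_class_test_set_raises(self):
        model = MajorityClassModel().fit(None, np.array([0, 1]))
        with pytest.raises(ValueError, match="single class"):
            evaluate(model, pd.DataFrame(index=range(4)), np.zeros(4, int))


class TestAblations:
    def test_arms_share_test_rows_and_report_all_five(self, small_matrix):
        split = split_by_user(small_matrix, seed=3)
        res = run_ablations(small_matrix, split, ModelConfig(seed=3))
        assert set(res.reports) == {"full", "no_estimate", "no_prior_brac",
                                    "estimate_only", "majority_class"}
        n_test = split.mask(small_matrix, "test").sum()
        for arm, s in res.test_scores.items():
            assert len(s) == n_test
        assert res.specs["estimate_only"].features == ["brac_estimate"]
        assert "brac_estimate" not in res.specs["no_estimate"].features
        assert all(not f.startswith(("prior_", "brac_lag", "disc_"))
                   for f in res.specs["no_prior_brac"].features)

    def test_missing_family_tags_raise(self, small_matrix):
        spec = FeatureSpec(features=["hour_of_day"],
                           families={"hour_of_day": "temporal"})
        split = split_by_user(small_matrix, seed=3)
        with pytest.raises(ConfigurationError, match="family"):
            run_ablations(small_matrix, split, ModelConfig(), spec)


class TestShap:
    def test_additivity_and_null_player(self):
        m = _toy_matrix(seed=7)
        clf = BracClassifier(n_estimators=30, seed=7).fit(
            m[TOY_SPEC.features], m["label_high"])
        imp = explain_shap(clf, m[TOY_SPEC.features].head(300))
        total = imp.base_value + imp.contributions.sum(axis=1)
        np.testing.assert_allclose(total, imp.margins, atol=1e-6)
        # a constant column is never split on -> exactly zero attribution
        k = imp.features.index("const")
        assert np.all(imp.contributions[:, k] == 0.0)

    def test_planted_dominant_feature_ranked_first(self):
        m = _toy_matrix(seed=9, informative=True)
        clf = BracClassifier(n_estimators=30, seed=9).fit(
            m[TOY_SPEC.features], m["label_high"])
        imp = explain_shap(clf, m[TOY_SPEC.features])
        assert imp.ranking()["feature"].iloc[0] == "sig"

    def test_non_tree_model_rejected(self):
        with pytest.raises(TypeError, match="tree"):
            explain_shap(MajorityClassModel(), pd.DataFrame({"x": [1.0]}))


class TestBootstrap:
    def test_identical_scores_are_a_tie(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 400)
        y[:5] = 1; y[5:10] = 0
        s = rng.random(400)
        users = np.repeat([f"u{i}" for i in range(40)], 10)
        out = paired_bootstrap_auc(y, s, s, users, n_boot=100, seed=1)
        assert out["delta"] == 0.0
        assert out["ci_low"] == out["ci_high"] == 0.0

    def test_detects_a_clearly_better_score(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 600)
        good = y + rng.normal(0, 0.4, 600)
        bad = rng.random(600)
        users = np.repeat([f"u{i}" for i in range(60)], 10)
        out = paired_bootstrap_auc(y, good, bad, users, n_boot=200, seed=2)
        assert out["delta"] > 0.2
        assert out["p_one_sided"] < 0.05


def test_determinism_of_training(small_matrix, default_spec):
    split = split_by_user(small_matrix, seed=4)
    r1 = run_ablations(small_matrix, split, ModelConfig(seed=4)).table()
    r2 = run_ablations(small_matrix, split, ModelConfig(seed=4)).table()
    pd.testing.assert_frame_equal(r1, r2)
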