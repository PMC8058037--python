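"""Class-balanced stochastic gradient-boosted classification trees.

User-level 70/10/20 splitting, a sklearn-style LightGBM wrapper with
inverse-frequency class weighting and early stopping on validation
log-loss, confusion-matrix evaluation, the nested feature-ablation suite,
exact TreeSHAP explanations, and paired user-bootstrap AUC comparisons.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import lightgbm as lgb
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import f1_score, roc_auc_score

from .config import ConfigurationError, ModelConfig
from .features import FeatureSpec

__all__ = ["SplitAssignment", "split_by_user", "BracClassifier",
           "MajorityClassModel", "EvaluationReport", "evaluate",
           "train_gbct", "run_ablations", "explain_shap",
           "paired_bootstrap_auc", "ABLATION_ARMS"]

#: Ablation arms: name -> families removed (None = not family-based).
ABLATION_ARMS = {
    "full": [],
    "no_estimate": ["estimate"],
    "no_prior_brac": ["prior_brac", "lag", "discrimination"],
    "estimate_only": None,
    "majority_class": None,
}


@dataclass
class SplitAssignment:
    """Per-user train/validation/test assignment (disjoint, exhaustive)."""

    assignment: pd.Series          # index: user_id, values in {train,validation,test}
    proportions: tuple
    seed: int

    def mask(self, matrix: pd.DataFrame, part: str) -> np.ndarray:
        return matrix["user_id"].map(self.assignment).to_numpy() == part

    def users(self, part: str) -> list:
        return list(self.assignment.index[self.assignment == part])


def split_by_user(matrix: pd.DataFrame,
                  proportions: tuple = (0.70, 0.10, 0.20),
                  seed: int = 0) -> SplitAssignment:
    """Randomly assign whole users to train/validation/test.

    Counts follow the largest-remainder rule so that e.g. 10 users at
    (0.7, 0.1, 0.2) give exactly 7/1/2.  All records of a user share one
    split; the assignment is deterministic under ``seed``.
    """
    if not np.isclose(sum(proportions), 1.0):
        raise ConfigurationError(f"split proportions {proportions} must sum to 1")
    users = pd.unique(matrix["user_id"])
    if len(users) < 3:
        raise ValueError("need at least 3 distinct users to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(users))
    n = len(users)
    raw = np.array(proportions) * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - np.floor(raw)))
    for i in range(rem):
        counts[order[i]] += 1
    labels = np.repeat(["train", "validation", "test"], counts)
    assignment = pd.Series(labels, index=users[perm], name="split")
    return SplitAssignment(assignment=assignment, proportions=tuple(proportions),
                           seed=seed)


class BracClassifier(BaseEstimator, ClassifierMixin):
    """Gradient-boosted tree classifier of high (>=0.08 g/dL) BrAC readings.

    A thin sklearn-style wrapper over LightGBM with the study model's
    settings: learning rate 0.1, up to ``n_estimators`` trees with early
    stopping on validation binary log-loss, L1/L2 regularization, and class
    weights inversely proportional to training class frequencies
    (n_total / (2 * n_class)).
    """

    def __init__(self, learning_rate: float = 0.1, n_estimators: int = 89,
                 l1: float = 0.5, l2: float = 0.5,
                 early_stopping_rounds: int = 5, class_balancing: bool = True,
                 decision_threshold: float = 0.5, bagging_fraction: float = 1.0,
                 num_leaves: int = 31, seed: int = 0):
        self.learning_rate = learning_rate
        self.n_estimators = n_estimators
        self.l1 = l1
        self.l2 = l2
        self.early_stopping_rounds = early_stopping_rounds
        self.class_balancing = class_balancing
        self.decision_threshold = decision_threshold
        self.bagging_fraction = bagging_fraction
        self.num_leaves = num_leaves
        self.seed = seed

    @classmethod
    def from_config(cls, config: ModelConfig) -> "BracClassifier":
        config.validate()
        return cls(learning_rate=config.learning_rate,
                   n_estimators=config.n_estimators, l1=config.l1,
                   l2=config.l2,
                   early_stopping_rounds=config.early_stopping_rounds,
                   class_balancing=config.class_balancing,
                   decision_threshold=config.decision_threshold,
                   bagging_fraction=config.bagging_fraction,
                   num_leaves=config.num_leaves, seed=config.seed)

    def fit(self, X, y, eval_set=None):
        X = self._as_frame(X)
        y = np.asarray(y, int)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError(
                f"training data contains a single class (counts: "
                f"{dict(zip(classes.tolist(), counts.tolist()))})")
        params = dict(
            objective="binary",
            learning_rate=self.learning_rate,
            n_estimators=self.n_estimators,
            reg_alpha=self.l1,
            reg_lambda=self.l2,
            num_leaves=self.num_leaves,
            subsample=self.bagging_fraction,
            subsample_freq=1 if self.bagging_fraction < 1.0 else 0,
            class_weight="balanced" if self.class_balancing else None,
            random_state=self.seed,
            deterministic=True,
            force_row_wise=True,
            n_jobs=1,
            verbose=-1,
        )
        model = lgb.LGBMClassifier(**params)
        fit_kw = {}
        if eval_set is not None:
            Xv, yv = eval_set
            fit_kw = dict(
                eval_set=[(self._as_frame(Xv), np.asarray(yv, int))],
                eval_metric="binary_logloss",
                callbacks=[lgb.early_stopping(self.early_stopping_rounds,
                                              verbose=False)],
            )
        model.fit(X, y, **fit_kw)
        self.model_ = model
        self.booster_ = model.booster_
        self.classes_ = model.classes_
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = list(X.columns)
        self.best_iteration_ = model.best_iteration_
        return self

    @staticmethod
    def _as_frame(X):
        if isinstance(X, pd.DataFrame):
            return X
        return pd.DataFrame(np.asarray(X, float))

    def predict_proba(self, X):
        return self.model_.predict_proba(self._as_frame(X))

    def decision_margin(self, X):
        """Raw log-odds margin of the ensemble (the scale SHAP sums to)."""
        return self.booster_.predict(self._as_frame(X), raw_score=True)

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        return (p >= self.decision_threshold).astype(int)


class MajorityClassModel:
    """Constant predictor of the most frequent training class."""

    def fit(self, X, y, eval_set=None):
        y = np.asarray(y, int)
        vals, counts = np.unique(y, return_counts=True)
        self.majority_ = int(vals[np.argmax(counts)])
        self.prevalence_ = float(np.mean(y))
        return self

    def predict_proba(self, X):
        n = len(X)
        p1 = np.full(n, self.prevalence_)
        return np.c_[1 - p1, p1]

    def predict(self, X):
        return np.full(len(X), self.majority_, int)


@dataclass
class EvaluationReport:
    """Test-set performance of one model arm."""

    arm: str
    roc_auc: float
    accuracy: float
    macro_f1: float
    sensitivity: float
    specificity: float
    precision: float | None          # None when no positive predictions
    tn: int
    fp: int
    fn: int
    tp: int
    n: int = field(default=0)

    def __post_init__(self):
        if self.n == 0:
            self.n = self.tn + self.fp + self.fn + self.tp
        assert self.tn + self.fp + self.fn + self.tp == self.n

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        if d["precision"] is None:
            d["precision"] = "Undefined"
        return d


def evaluate(model, X, y, threshold: float | None = None,
             arm: str = "model") -> EvaluationReport:
    """Confusion-matrix metrics at the decision threshold, AUC by midrank.

    Precision with zero positive predictions is reported as undefined
    (None), not 0.  Requires both classes present in ``y``.
    """
    y = np.asarray(y, int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: test labels contain a single class")
    scores = model.predict_proba(X)[:, 1]
    auc = float(roc_auc_score(y, scores))
    thr = (threshold if threshold is not None
           else getattr(model, "decision_threshold", 0.5))
    pred = (scores >= thr).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    prec = tp / (tp + fp) if (tp + fp) > 0 else None
    acc = (tp + tn) / len(y)
    macro = float(f1_score(y, pred, average="macro", zero_division=0))
    return EvaluationReport(arm=arm, roc_auc=auc, accuracy=acc, macro_f1=macro,
                            sensitivity=sens, specificity=spec, precision=prec,
                            tn=tn, fp=fp, fn=fn, tp=tp)


def _parts(matrix, split, spec):
    X = matrix[spec.features]
    y = matrix["label_high"].to_numpy(int)
    tr = split.mask(matrix, "train")
    va = split.mask(matrix, "validation")
    te = split.mask(matrix, "test")
    return X, y, tr, va, te


def train_gbct(matrix: pd.DataFrame, split: SplitAssignment,
               config: ModelConfig, spec: FeatureSpec) -> BracClassifier:
    """Fit the boosted-tree model on the training users, early-stopping on
    the validation users."""
    missing = [f for f in spec.features if f not in matrix.columns]
    if missing:
        raise ConfigurationError(f"matrix lacks feature column(s): {missing}")
    X, y, tr, va, te = _parts(matrix, split, spec)
    clf = BracClassifier.from_config(config)
    eval_set = (X[va], y[va]) if va.any() else None
    return clf.fit(X[tr], y[tr], eval_set=eval_set)


@dataclass
class AblationResult:
    reports: dict                      # arm -> EvaluationReport
    test_scores: dict                  # arm -> np.ndarray of P(high) on test rows
    test_labels: np.ndarray
    test_users: np.ndarray
    specs: dict                        # arm -> FeatureSpec or None

    def table(self) -> pd.DataFrame:
        rows = [r.to_dict() for r in self.reports.values()]
        return pd.DataFrame(rows).set_index("arm")


def run_ablations(matrix: pd.DataFrame, split: SplitAssignment,
                  config: ModelConfig, spec: FeatureSpec | None = None
                  ) -> AblationResult:
    """Train and evaluate the five nested arms on one shared split.

    full; all-but-estimate; all-but-prior-BrAC-history; estimate-only; and
    the constant majority-class baseline.  All arms score the identical
    test rows.
    """
    spec = spec or FeatureSpec()
    for fam in ("estimate", "prior_brac"):
        if fam not in set(spec.families.values()):
            raise ConfigurationError(
                f"feature spec tags no '{fam}' family; ablation arms undefined")
    y = matrix["label_high"].to_numpy(int)
    te = split.mask(matrix, "test")
    reports, scores, specs = {}, {}, {}
    for arm, removed in ABLATION_ARMS.items():
        if arm == "estimate_only":
            arm_spec = spec.only(["brac_estimate"])
        elif arm == "majority_class":
            arm_spec = None
        else:
            arm_spec = spec.without_families(removed)
        specs[arm] = arm_spec
        if arm_spec is None:
            model = MajorityClassModel()
            tr = split.mask(matrix, "train")
            model.fit(None, y[tr])
            Xte = matrix.loc[te, spec.features]
        else:
            model = train_gbct(matrix, split, config, arm_spec)
            Xte = matrix.loc[te, arm_spec.features]
        reports[arm] = evaluate(model, Xte, y[te],
                                threshold=config.decision_threshold, arm=arm)
        scores[arm] = model.predict_proba(Xte)[:, 1]
    return AblationResult(reports=reports, test_scores=scores,
                          test_labels=y[te],
                          test_users=matrix.loc[te, "user_id"].to_numpy(),
                          specs=specs)


@dataclass
class ImportanceReport:
    """Per-feature Shapley attribution summary on the test rows."""

    features: list
    mean_abs_shap: np.ndarray
    mean_shap: np.ndarray
    base_value: float
    contributions: np.ndarray          # (n_rows, n_features)
    margins: np.ndarray                # raw model output per row

    def ranking(self) -> pd.DataFrame:
        df = pd.DataFrame({"feature": self.features,
                           "mean_abs_shap": self.mean_abs_shap,
                           "mean_shap": self.mean_shap})
        return df.sort_values("mean_abs_shap", ascending=False,
                              ignore_index=True)


def explain_shap(model, X: pd.DataFrame) -> ImportanceReport:
    """Exact tree-path Shapley attributions (TreeSHAP) for a fitted arm.

    Uses the boosted ensemble's own path-dependent TreeSHAP; per row the
    base value plus the attributions equals the raw log-odds margin.
    """
    booster = getattr(model, "booster_", None)
    if booster is None:
        raise TypeError("SHAP explanation requires a fitted tree model "
                        "(BracClassifier)")
    X = model._as_frame(X)
    contrib = booster.predict(X, pred_contrib=True)
    phi, base = contrib[:, :-1], contrib[:, -1]
    margins = booster.predict(X, raw_score=True)
    return ImportanceReport(
        features=list(X.columns),
        mean_abs_shap=np.abs(phi).mean(axis=0),
        mean_shap=phi.mean(axis=0),
        base_value=float(base[0]) if len(base) else 0.0,
        contributions=phi,
        margins=margins,
    )


def paired_bootstrap_auc(labels, scores_a, scores_b, users,
                         n_boot: int = 500, seed: int = 0) -> dict:
    """Paired user-level bootstrap of AUC(a) - AUC(b) on one test set.

    Resamples test users with replacement, recomputing both AUCs on the
    same resample.  Returns the observed difference, a percentile CI, and
    the one-sided p-value for the hypothesis that a is no better than b.
    """
    labels = np.asarray(labels, int)
    sa, sb = np.asarray(scores_a, float), np.asarray(scores_b, float)
    users = np.asarray(users)
    uniq = pd.unique(users)
    idx_by_user = {u: np.flatnonzero(users == u) for u in uniq}
    rng = np.random.default_rng(seed)
    obs = roc_auc_score(labels, sa) - roc_auc_score(labels, sb)
    deltas = []
    while len(deltas) < n_boot:
        pick = rng.choice(len(uniq), size=len(uniq), replace=True)
        idx = np.concatenate([idx_by_user[uniq[i]] for i in pick])
        yb = labels[idx]
        if yb.min() == yb.max():
            continue
        deltas.append(roc_auc_score(yb, sa[idx]) - roc_auc_score(yb, sb[idx]))
    deltas = np.asarray(deltas)
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    p_one_sided = float(np.mean(deltas <= 0))
    return {"delta": float(obs), "ci_low": float(lo), "ci_high": float(hi),
            "p_one_sided": p_one_sided, "n_boot": int(n_boot)}
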