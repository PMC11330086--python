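"""Uniform interface over the six supervised learner families.

The same families serve four roles in the pipeline: scoring candidate
thresholds in automated filtering, scoring feature subsets during selection,
producing the model behind SHAP-based grouping, and fitting the cluster-label
model for interpretation. Naive Bayes and logistic regression are
classification-only.

Default hyperparameters (overridable through LearnerSpec.hyperparameters):
random_forest 500 trees; gradient_boosted_trees (LightGBM) 100 boosting
rounds, 31 leaves; svm RBF kernel with probability calibration; knn k=5;
naive_bayes Gaussian; logistic_regression L2, max_iter=1000.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

# lightgbm's sklearn wrapper invents feature names for bare arrays and then
# warns on every predict; harmless noise for our ndarray-only interface
warnings.filterwarnings(
    "ignore", message="X does not have valid feature names"
)
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, r2_score, roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.svm import SVC, SVR
import lightgbm as lgb

FAMILIES = (
    "random_forest",
    "gradient_boosted_trees",
    "svm",
    "knn",
    "naive_bayes",
    "logistic_regression",
)
CLASSIFICATION_ONLY = ("naive_bayes", "logistic_regression")
METRICS = ("accuracy", "auc", "r2")


@dataclass
class LearnerSpec:
    family: str = "gradient_boosted_trees"
    task: str = "classification"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown learner family {self.family!r}")
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.family in CLASSIFICATION_ONLY and self.task == "regression":
            raise ValueError(
                f"{self.family} is only available for classification"
            )

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "task": self.task,
            "hyperparameters": dict(self.hyperparameters),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LearnerSpec":
        return cls(
            family=d["family"],
            task=d["task"],
            hyperparameters=dict(d.get("hyperparameters", {})),
            seed=int(d.get("seed", 0)),
        )


def _build_estimator(spec: LearnerSpec):
    hp = dict(spec.hyperparameters)
    seed = spec.seed
    clf = spec.task == "classification"
    if spec.family == "random_forest":
        cls = RandomForestClassifier if clf else RandomForestRegressor
        return cls(n_estimators=hp.pop("n_estimators", 500), random_state=seed,
                   n_jobs=1, **hp)
    if spec.family == "gradient_boosted_trees":
        cls = lgb.LGBMClassifier if clf else lgb.LGBMRegressor
        return cls(
            n_estimators=hp.pop("n_estimators", 100),
            num_leaves=hp.pop("num_leaves", 31),
            random_state=seed,
            n_jobs=1,
            verbose=-1,
            **hp,
        )
    if spec.family == "svm":
        if clf:
            return SVC(probability=True, random_state=seed,
                       kernel=hp.pop("kernel", "rbf"), **hp)
        return SVR(kernel=hp.pop("kernel", "rbf"), **hp)
    if spec.family == "knn":
        cls = KNeighborsClassifier if clf else KNeighborsRegressor
        return cls(n_neighbors=hp.pop("n_neighbors", 5), **hp)
    if spec.family == "naive_bayes":
        return GaussianNB(**hp)
    if spec.family == "logistic_regression":
        return LogisticRegression(max_iter=hp.pop("max_iter", 1000),
                                  random_state=seed, **hp)
    raise ValueError(spec.family)


class FittedLearner:
    """A fitted estimator bound to the column names it was trained on."""

    def __init__(self, spec: LearnerSpec, estimator, column_names: list[str],
                 X: np.ndarray, y: np.ndarray):
        self.spec = spec
        self.estimator = estimator
        self.column_names = list(column_names)
        self._X_train = X
        self._y_train = y

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.column_names):
            raise ValueError(
                f"expected {len(self.column_names)} columns, got {X.shape[1]}"
            )
        return X

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(self._check(X))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.spec.task != "classification":
            raise ValueError("predict_proba requires a classification task")
        return self.estimator.predict_proba(self._check(X))

    def margin(self, X: np.ndarray) -> np.ndarray:
        """Raw model output: regression prediction or classification margin."""
        X = self._check(X)
        if self.spec.task == "regression":
            return self.estimator.predict(X)
        if self.spec.family == "gradient_boosted_trees":
            return self.estimator.predict(X, raw_score=True)
        if hasattr(self.estimator, "decision_function"):
            return self.estimator.decision_function(X)
        proba = self.estimator.predict_proba(X)
        with np.errstate(divide="ignore"):
            return np.log(np.clip(proba, 1e-12, None))[:, -1]

    def importances(self, seed: int | None = None) -> np.ndarray:
        """Feature-importance ranking source for RFE.

        Model-native importances for tree ensembles, |coefficients| for
        linear models, permutation importance (on the training data,
        seeded) for KNN / SVM / naive Bayes.
        """
        est = self.estimator
        if hasattr(est, "feature_importances_"):
            return np.asarray(est.feature_importances_, dtype=float)
        if hasattr(est, "coef_"):
            coef = np.atleast_2d(est.coef_)
            return np.abs(coef).mean(axis=0)
        seed = self.spec.seed if seed is None else seed
        res = permutation_importance(
            est, self._X_train, self._y_train, n_repeats=5, random_state=seed,
            n_jobs=1,
        )
        return np.asarray(res.importances_mean, dtype=float)


class Learner:
    """Unfitted learner factory produced by :func:`make_learner`."""

    def __init__(self, spec: LearnerSpec):
        self.spec = spec

    def fit(self, X: np.ndarray, y: np.ndarray,
            column_names: list[str] | None = None) -> FittedLearner:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        est = _build_estimator(self.spec)
        est.fit(X, y)
        names = (list(column_names) if column_names is not None
                 else [f"x{i}" for i in range(X.shape[1])])
        return FittedLearner(self.spec, est, names, X, y)


def make_learner(spec: LearnerSpec) -> Learner:
    _build_estimator(spec)  # validate family/task/hyperparameters eagerly
    return Learner(spec)


def _check_metric(spec: LearnerSpec, metric: str) -> None:
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if metric in ("accuracy", "auc") and spec.task != "classification":
        raise ValueError(f"metric {metric!r} requires a classification task")
    if metric == "r2" and spec.task != "regression":
        raise ValueError("metric 'r2' requires a regression task")


def _score(spec: LearnerSpec, fitted: FittedLearner, X: np.ndarray,
           y: np.ndarray, metric: str) -> float:
    if metric == "accuracy":
        return float(accuracy_score(y, fitted.predict(X)))
    if metric == "r2":
        return float(r2_score(y, fitted.predict(X)))
    proba = fitted.predict_proba(X)
    if proba.shape[1] == 2:
        return float(roc_auc_score(y, proba[:, 1]))
    # multiclass: one-vs-rest macro average
    return float(roc_auc_score(y, proba, multi_class="ovr", average="macro"))


def default_metric(task: str) -> str:
    return "auc" if task == "classification" else "r2"


def cv_score(
    spec: LearnerSpec,
    X: np.ndarray,
    y: np.ndarray,
    metric: str,
    k_folds: int = 5,
    seed: int = 0,
) -> float:
    """Mean held-out metric over stratified (classification) or plain folds."""
    _check_metric(spec, metric)
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if spec.task == "classification":
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < k_folds:
            raise ValueError(
                "smallest class has fewer members than folds; cannot stratify"
            )
        splitter = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    learner = make_learner(spec)
    scores = []
    for train_idx, test_idx in splitter.split(X, y):
        fitted = learner.fit(X[train_idx], y[train_idx])
        scores.append(_score(spec, fitted, X[test_idx], y[test_idx], metric))
    return float(np.mean(scores))


def holdout_score(
    spec: LearnerSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    metric: str,
) -> float:
    """Single train/test evaluation used by the 80/20 automated filter search."""
    _check_metric(spec, metric)
    fitted = make_learner(spec).fit(X_train, y_train)
    return _score(spec, fitted, X_test, y_test, metric)
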