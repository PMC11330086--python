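"""Shapley-value attributions for the supported learner families.

Three computation routes, chosen by model family:

- exact tree attributions for the gradient-boosted-trees family, via
  LightGBM's native per-feature contribution output (TreeSHAP); row sums
  plus the base value reproduce the model margin exactly;
- closed-form linear Shapley values for logistic regression,
  phi_ij = w_j * (x_ij - mean_j(background)), exact for linear models;
- seeded permutation-sampling Shapley values for the remaining families,
  model-agnostic against a fixed background sample. The telescoping sum
  makes these satisfy the efficiency axiom exactly per sample; symmetry
  holds up to sampling noise.

Binary classification keeps the positive-class attribution block only;
multiclass problems concatenate per-class blocks column-wise (n x p*C).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from chemgroup.descriptors import FeatureMatrix
from chemgroup.learners import FittedLearner


@dataclass
class ShapMatrix:
    """Per-compound, per-descriptor attribution values from a fitted learner.

    ``values`` is n x p for regression and binary classification (positive
    class), or n x (p*C) for C-class problems with class blocks concatenated
    and column names suffixed ``__class{c}``.
    """

    values: np.ndarray
    base_values: np.ndarray  # one entry per class block (length 1 or C)
    column_names: list[str]
    feature_names: list[str]
    learner_spec: dict
    classes: list | None = None  # class values for classification, else None

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def n_blocks(self) -> int:
        return self.values.shape[1] // self.n_features

    def block(self, class_index: int) -> np.ndarray:
        """n x p attribution block for one class.

        With a single stored block (binary classification), the negative
        class block is the negation of the positive one.
        """
        p = self.n_features
        if self.n_blocks == 1:
            if self.classes is not None and len(self.classes) == 2 and class_index == 0:
                return -self.values
            return self.values
        return self.values[:, class_index * p : (class_index + 1) * p]


def _tree_shap(fitted: FittedLearner, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """LightGBM native contributions: (n, blocks*(p+1)) -> (values, bases)."""
    booster = fitted.estimator.booster_ if hasattr(fitted.estimator, "booster_") else fitted.estimator
    contrib = booster.predict(X, pred_contrib=True)
    p = X.shape[1]
    width = p + 1
    n_blocks = contrib.shape[1] // width
    blocks, bases = [], []
    for b in range(n_blocks):
        chunk = contrib[:, b * width : (b + 1) * width]
        blocks.append(chunk[:, :p])
        bases.append(float(chunk[0, p]))
    return np.hstack(blocks), np.asarray(bases)


def _linear_shap(
    fitted: FittedLearner, X: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    coef = np.atleast_2d(fitted.estimator.coef_)
    intercept = np.atleast_1d(fitted.estimator.intercept_)
    mu = background.mean(axis=0)
    blocks, bases = [], []
    for c in range(coef.shape[0]):
        blocks.append(coef[c] * (X - mu))
        bases.append(float(coef[c] @ mu + intercept[c]))
    return np.hstack(blocks), np.asarray(bases)


def _sampling_shap(
    fitted: FittedLearner,
    X: np.ndarray,
    background: np.ndarray,
    n_classes: int,
    n_permutations: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation-sampling Shapley values against a background sample."""
    rng = np.random.default_rng(seed)
    n, p = X.shape

    def value(rows: np.ndarray) -> np.ndarray:
        # (m,) for regression/binary-positive, or (m, C) multiclass
        if n_classes == 0:
            return fitted.predict(rows)
        proba = fitted.predict_proba(rows)
        return proba[:, 1] if n_classes == 2 else proba

    n_out = 1 if n_classes in (0, 2) else n_classes
    phi = np.zeros((n, p * n_out))
    bg_idx = rng.integers(len(background), size=n_permutations)
    perms = [rng.permutation(p) for _ in range(n_permutations)]

    for i in range(n):
        x = X[i]
        contrib = np.zeros((p, n_out))
        for m in range(n_permutations):
            perm = perms[m]
            z = background[bg_idx[m]].copy()
            rows = np.empty((p + 1, p))
            rows[0] = z
            for step, j in enumerate(perm):
                z = z.copy()
                z[j] = x[j]
                rows[step + 1] = z
            vals = value(rows).reshape(p + 1, n_out)
            contrib[perm] += vals[1:] - vals[:-1]
        contrib /= n_permutations
        phi[i] = contrib.T.reshape(-1)

    # base = mean value over the sampled background rows; the telescoping sum
    # then gives sum(phi) + base = f(x) exactly per sample
    sampled_base = np.atleast_2d(
        value(background[bg_idx]).reshape(n_permutations, -1)
    ).mean(axis=0)
    return phi, sampled_base


def compute_shap(
    fitted: FittedLearner,
    fm: FeatureMatrix,
    n_permutations: int = 20,
    background_size: int = 50,
    seed: int | None = None,
) -> ShapMatrix:
    """SHAP attribution matrix for a fitted learner on ``fm``'s rows.

    Exact tree-path attribution for the gradient-boosted-trees family,
    closed-form values for logistic regression, and a seeded sampling
    approximation with a fixed background sample otherwise.
    """
    if list(fm.column_names) != list(fitted.column_names):
        raise ValueError("feature matrix columns do not match the fitted learner")
    X = fm.values
    seed = fitted.spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    bg = fitted._X_train
    if len(bg) > background_size:
        bg = bg[rng.choice(len(bg), size=background_size, replace=False)]

    classes = None
    if fitted.spec.task == "classification":
        classes = [c for c in np.asarray(fitted.estimator.classes_).tolist()]

    family = fitted.spec.family
    if family == "gradient_boosted_trees":
        values, bases = _tree_shap(fitted, X)
    elif family == "logistic_regression":
        values, bases = _linear_shap(fitted, X, bg)
        if classes is not None and len(classes) == 2 and values.shape[1] > len(fm.column_names):
            values = values[:, -len(fm.column_names):]
            bases = bases[-1:]
    else:
        n_classes = 0 if classes is None else len(classes)
        values, bases = _sampling_shap(
            fitted, X, bg, n_classes, n_permutations, seed
        )

    p = len(fm.column_names)
    n_blocks = values.shape[1] // p
    if n_blocks == 1:
        col_names = list(fm.column_names)
    else:
        col_names = [
            f"{c}__class{classes[b]}" for b in range(n_blocks) for c in fm.column_names
        ]
    return ShapMatrix(
        values=values,
        base_values=np.asarray(bases, dtype=float),
        column_names=col_names,
        feature_names=list(fm.column_names),
        learner_spec=fitted.spec.to_dict(),
        classes=classes,
    )
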