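"""Self-implemented binary classifiers and leave-one-out evaluation.

Two classifiers predict the vasoplegia group from fold-change features:

* ridge-penalized logistic regression fitted by iteratively reweighted
  least squares (IRLS / Newton), with the penalty on the non-intercept
  coefficients only;
* gradient-boosted regression trees under the logistic loss, initialized
  at the base-rate log-odds, with leaf values given by a Newton step
  (-sum g / sum h) scaled by the learning rate; the default weak learner
  is a depth-1 stump whose split is found by exact scan over midpoints
  of the sorted unique feature values.

Evaluation is leave-one-out: n fits, the i-th trained without patient i
and tested on patient i.  The headline error is the mean absolute error
of hard 0/1 predictions at a 0.5 threshold — i.e. the misclassification
rate — with the probability-based MAE also reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "ClassifierSpec",
    "LogisticModel",
    "fit_logistic",
    "GBTModel",
    "fit_gbt",
    "LOOResult",
    "loo_evaluate",
]


@dataclass
class ClassifierSpec:
    """Hyperparameters of the two classifiers."""

    method: str = "logistic"  # "logistic" | "gbt"
    l2: float = 0.0           # ridge penalty on non-intercept coefficients
    rounds: int = 100         # boosting iterations
    learning_rate: float = 0.1
    max_depth: int = 1
    threshold: float = 0.5    # decision cutoff on predicted probability

    def validate(self) -> None:
        if self.method not in ("logistic", "gbt"):
            raise ValidationError(f"unknown method {self.method!r}")
        if self.l2 < 0:
            raise ValidationError("l2 must be >= 0")
        if self.rounds < 1:
            raise ValidationError("rounds must be >= 1")
        if not 0 < self.learning_rate <= 1:
            raise ValidationError("learning_rate must be in (0, 1]")
        if self.max_depth < 1:
            raise ValidationError("max_depth must be >= 1")
        if not 0 < self.threshold < 1:
            raise ValidationError("threshold must be in (0, 1)")


def _as_design(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class LogisticModel:
    intercept: float
    coef: np.ndarray
    l2: float
    converged: bool
    n_iter: int

    def decision(self, x) -> np.ndarray:
        return self.intercept + _as_design(x) @ self.coef

    def predict_proba(self, x) -> np.ndarray:
        return _sigmoid(self.decision(x))


def fit_logistic(x, y, l2: float = 0.0, tol: float = 1e-8, max_iter: int = 100) -> LogisticModel:
    """Maximize the ridge-penalized Bernoulli log-likelihood by IRLS.

    The objective is sum_i [y_i log p_i + (1-y_i) log(1-p_i)]
    - (l2/2) * ||slope||^2; the intercept is not penalized.  Convergence
    is declared when the max coefficient change drops below ``tol``;
    perfectly separable data with l2 = 0 never converge and come back
    flagged (``converged=False``) with the coefficients at iteration
    ``max_iter`` — callers wanting a finite optimum refit with a small
    ridge.
    """
    X = _as_design(x)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n < 2:
        raise ValidationError("logistic fit needs n >= 2")
    if len(np.unique(y)) < 2:
        raise ValidationError("logistic fit needs both classes present")
    if l2 < 0:
        raise ValidationError("l2 must be >= 0")

    D = np.column_stack([np.ones(n), X])
    beta = np.zeros(k + 1)
    penalty = np.diag([0.0] + [l2] * k)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = _sigmoid(D @ beta)
        w = p * (1 - p)
        grad = D.T @ (y - p) - penalty @ beta
        hess = (D.T * w) @ D + penalty
        # ridge-free separable fits drive w -> 0; regularize the solve only
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    return LogisticModel(float(beta[0]), beta[1:], l2, converged, it)


@dataclass
class _TreeNode:
    value: float | None = None        # leaf value (None for internal nodes)
    feature: int = 0
    threshold: float = 0.0
    left: "_TreeNode | None" = None
    right: "_TreeNode | None" = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.value is not None:
            return np.full(len(X), self.value)
        mask = X[:, self.feature] <= self.threshold
        out = np.empty(len(X))
        out[mask] = self.left.predict(X[mask])
        out[~mask] = self.right.predict(X[~mask])
        return out


def _leaf_value(g: np.ndarray, h: np.ndarray) -> float:
    hs = float(h.sum())
    return 0.0 if hs <= 0 else float(-g.sum() / hs)


def _fit_tree(X: np.ndarray, g: np.ndarray, h: np.ndarray, depth: int) -> _TreeNode:
    """Greedy regression tree on (gradient, hessian); exact split scan."""
    if depth == 0 or len(g) < 2:
        return _TreeNode(value=_leaf_value(g, h))

    G, H = float(g.sum()), float(h.sum())
    base_score = G * G / H if H > 0 else 0.0
    best_gain, best = 1e-12, None
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        xs, gs, hs = X[order, j], g[order], h[order]
        gl = np.cumsum(gs)[:-1]
        hl = np.cumsum(hs)[:-1]
        valid = xs[1:] > xs[:-1]
        if not valid.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.where(hl > 0, gl**2 / hl, 0.0) + np.where(
                H - hl > 0, (G - gl) ** 2 / (H - hl), 0.0
            )
        score = np.where(valid, score - base_score, -np.inf)
        i = int(np.argmax(score))
        if score[i] > best_gain:
            best_gain = float(score[i])
            best = (j, (xs[i] + xs[i + 1]) / 2.0)
    if best is None:
        return _TreeNode(value=_leaf_value(g, h))
    j, thr = best
    mask = X[:, j] <= thr
    return _TreeNode(
        feature=j,
        threshold=thr,
        left=_fit_tree(X[mask], g[mask], h[mask], depth - 1),
        right=_fit_tree(X[~mask], g[~mask], h[~mask], depth - 1),
    )


@dataclass
class GBTModel:
    f0: float
    trees: list[_TreeNode] = field(default_factory=list)
    learning_rate: float = 0.1

    def decision(self, x) -> np.ndarray:
        X = _as_design(x)
        f = np.full(len(X), self.f0)
        for tree in self.trees:
            f += self.learning_rate * tree.predict(X)
        return f

    def predict_proba(self, x) -> np.ndarray:
        return _sigmoid(self.decision(x))


def fit_gbt(x, y, spec: ClassifierSpec | None = None) -> GBTModel:
    """Gradient boosting with logistic loss.

    Round t fits a depth-``max_depth`` tree to the negative gradient of
    the logistic loss at the current scores (g_i = p_i - y_i,
    h_i = p_i (1 - p_i)); each leaf takes the Newton step -sum g / sum h
    scaled by the learning rate.  The initial score is the log-odds of
    the base rate.
    """
    spec = spec or ClassifierSpec(method="gbt")
    spec.validate()
    X = _as_design(x)
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        raise ValidationError("gbt fit needs n >= 2")
    if len(np.unique(y)) < 2:
        raise ValidationError("gbt fit needs both classes present")

    base = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
    model = GBTModel(f0=math.log(base / (1 - base)), learning_rate=spec.learning_rate)
    f = np.full(len(y), model.f0)
    for _ in range(spec.rounds):
        p = _sigmoid(f)
        g = p - y
        h = p * (1 - p)
        tree = _fit_tree(X, g, h, spec.max_depth)
        model.trees.append(tree)
        f += spec.learning_rate * tree.predict(X)
    return model


def _fit(x, y, spec: ClassifierSpec):
    if spec.method == "logistic":
        model = fit_logistic(x, y, l2=spec.l2)
        if not model.converged and spec.l2 == 0.0:
            # separable data: the unpenalized optimum is at infinity
            model = fit_logistic(x, y, l2=1e-4)
        return model
    return fit_gbt(x, y, spec)


@dataclass
class LOOResult:
    table: pd.DataFrame  # patient_id, y_true, probability, y_pred
    mae: float
    mae_probability: float
    misclassified: list[str]
    degenerate_folds: list[str]  # folds whose training set had one class


def loo_evaluate(x, y, ids=None, spec: ClassifierSpec | None = None) -> LOOResult:
    """Leave-one-out evaluation: n fits, each without one patient.

    If dropping a patient empties one class in a training fold, that
    fold predicts the training majority class and is flagged in
    ``degenerate_folds``.
    """
    spec = spec or ClassifierSpec()
    spec.validate()
    X = _as_design(x)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValidationError("leave-one-out needs n >= 3")
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present")
    ids = [str(i) for i in (ids if ids is not None else range(n))]
    if len(ids) != n or len(set(ids)) != n:
        raise ValidationError("ids must be unique and match the sample size")

    probs = np.empty(n)
    degenerate: list[str] = []
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        y_train = y[mask]
        if len(np.unique(y_train)) < 2:
            probs[i] = float(y_train.mean())
            degenerate.append(ids[i])
        else:
            model = _fit(X[mask], y_train, spec)
            probs[i] = float(model.predict_proba(X[i : i + 1])[0])
        mask[i] = True

    y_pred = (probs >= spec.threshold).astype(int)
    mae = float(np.mean(np.abs(y - y_pred)))
    mae_prob = float(np.mean(np.abs(y - probs)))
    table = pd.DataFrame(
        {"patient_id": ids, "y_true": y.astype(int), "probability": probs, "y_pred": y_pred}
    )
    misclassified = [ids[i] for i in range(n) if y_pred[i] != y[i]]
    return LOOResult(table, mae, mae_prob, misclassified, degenerate)
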