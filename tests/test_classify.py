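"""Classifiers vs brute-force/hand oracles and reference implementations."""

import numpy as np
import pytest

import vasokin.classify as vc
from vasokin.classify import (
    ClassifierSpec,
    fit_gbt,
    fit_logistic,
    loo_evaluate,
)
from vasokin.errors import ValidationError


def _penalized_loglik(x, y, b0, b1, l2):
    z = b0 + b1 * x
    return np.sum(y * z - np.logaddexp(0, z), axis=-1) - 0.5 * l2 * np.squeeze(b1, -1) ** 2


def _grid_optimum(x, y, l2):
    """Coarse-to-fine grid search maximum of the penalized likelihood."""
    b0, b1, half = 0.0, 0.0, 8.0
    for _ in range(7):
        b0s = np.linspace(b0 - half, b0 + half, 41)
        b1s = np.linspace(b1 - half, b1 + half, 41)
        ll = _penalized_loglik(
            x[None, None, :], y[None, None, :], b0s[:, None, None], b1s[None, :, None], l2
        )
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        b0, b1 = b0s[i], b1s[j]
        half /= 8.0
    return b0, b1


# ---------------------------------------------------------------- logistic
def test_logistic_symmetric_data_zero_intercept():
    x = np.array([-3.0, -2.0, -1.0, -0.5, 0.5, 1.0, 2.0, 3.0])
    y = (x > 0).astype(float)
    model = fit_logistic(x, y, l2=1e-4)
    assert abs(model.intercept) < 1e-6
    assert model.predict_proba(np.array([0.0]))[0] == pytest.approx(0.5)


def test_logistic_matches_grid_search_optimum():
    rng = np.random.default_rng(41)
    x = rng.normal(0, 1, 8)
    y = np.array([0, 0, 0, 1, 0, 1, 1, 1], float)
    l2 = 0.5
    model = fit_logistic(x, y, l2=l2)
    b0, b1 = _grid_optimum(x, y, l2)
    assert model.intercept == pytest.approx(b0, abs=1e-3)
    assert model.coef[0] == pytest.approx(b1, abs=1e-3)


def test_logistic_separable_without_ridge_is_flagged():
    x = np.array([-2.0, -1.0, 1.0, 2.0])
    y = np.array([0, 0, 1, 1], float)
    model = fit_logistic(x, y, l2=0.0)
    assert not model.converged
    assert fit_logistic(x, y, l2=1e-4).converged


def test_logistic_one_class_errors():
    with pytest.raises(ValidationError):
        fit_logistic([1.0, 2.0], [1, 1])


def test_logistic_matches_sklearn_ridge():
    """Cross-check IRLS coefficients against scikit-learn (C = 1/l2)."""
    from sklearn.linear_model import LogisticRegression

    rng = np.random.default_rng(43)
    x = rng.normal(0, 1, 20)
    y = (rng.random(20) < 1 / (1 + np.exp(-2 * x))).astype(float)
    l2 = 1.0
    mine = fit_logistic(x, y, l2=l2)
    ref = LogisticRegression(C=1 / l2, tol=1e-12, max_iter=10_000).fit(x[:, None], y)
    assert mine.intercept == pytest.approx(ref.intercept_[0], abs=1e-4)
    assert mine.coef[0] == pytest.approx(ref.coef_[0, 0], abs=1e-4)


# --------------------------------------------------------------------- gbt
def test_gbt_capacity_on_separable_data():
    x = np.array([-2.0, -1.5, -1.0, 1.0, 1.5, 2.0])
    y = np.array([0, 0, 0, 1, 1, 1], float)
    model = fit_gbt(x, y, ClassifierSpec(method="gbt", rounds=50, learning_rate=0.3))
    assert np.array_equal(model.predict_proba(x) >= 0.5, y.astype(bool))


def test_gbt_constant_feature_predicts_base_rate():
    x = np.zeros(10)
    y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], float)
    model = fit_gbt(x, y, ClassifierSpec(method="gbt", rounds=20))
    assert np.allclose(model.predict_proba(x), 0.3)


def test_gbt_single_round_newton_leaf_values():
    """One depth-1 round at lr 1: leaves carry -sum(g)/sum(h) by hand.

    x = [0,1,2,3], y = [0,0,1,1]: f0 = 0, p = 0.5, g = (0.5,0.5,-0.5,-0.5),
    h = 0.25 each; the split at 1.5 gives leaf values -2 and +2.
    """
    x = np.array([0.0, 1.0, 2.0, 3.0])
    y = np.array([0, 0, 1, 1], float)
    model = fit_gbt(x, y, ClassifierSpec(method="gbt", rounds=1, learning_rate=1.0))
    tree = model.trees[0]
    assert tree.threshold == pytest.approx(1.5)
    assert tree.left.value == pytest.approx(-2.0)
    assert tree.right.value == pytest.approx(2.0)
    assert model.decision(x) == pytest.approx([-2.0, -2.0, 2.0, 2.0])


def test_gbt_loo_agrees_with_xgboost(cd34_feature):
    """Hard-label LOO predictions match an equivalently configured xgboost."""
    import xgboost as xgb

    x, y, _ = cd34_feature
    spec = ClassifierSpec(method="gbt", rounds=50, learning_rate=0.1, max_depth=1)
    mine = loo_evaluate(x, y, spec=spec).table["y_pred"].to_numpy()

    theirs = np.empty(len(y), dtype=int)
    for i in range(len(y)):
        mask = np.arange(len(y)) != i
        clf = xgb.XGBClassifier(
            n_estimators=50,
            learning_rate=0.1,
            max_depth=1,
            reg_lambda=0.0,
            min_child_weight=0.0,
            gamma=0.0,
            base_score=float(y[mask].mean()),
            tree_method="exact",
        )
        clf.fit(x[mask, None], y[mask])
        theirs[i] = int(clf.predict_proba(x[i : i + 1, None])[0, 1] >= 0.5)
    assert np.mean(mine == theirs) >= 0.9


# --------------------------------------------------------------------- loo
def test_loo_performs_exactly_n_fits(monkeypatch, cd34_feature):
    x, y, ids = cd34_feature
    calls = []
    original = vc.fit_logistic

    def counting_fit(*args, **kwargs):
        calls.append(len(args[0]))
        return original(*args, **kwargs)

    monkeypatch.setattr(vc, "fit_logistic", counting_fit)
    loo_evaluate(x, y, ids, ClassifierSpec(method="logistic", l2=1e-4))
    assert len(calls) == 15
    assert all(n == 14 for n in calls)


def test_loo_mae_arithmetic():
    # y = (1,1,1,0,0): with one error the hard-label MAE is 1/5
    x = np.array([1.0, 2.0, 3.0, -1.0, -2.0])
    y = np.array([1, 1, 1, 0, 0])
    res = loo_evaluate(x, y, ["a", "b", "c", "d", "e"], ClassifierSpec(l2=1e-2))
    assert res.mae * len(y) == pytest.approx(round(res.mae * len(y)))
    assert len(res.misclassified) == round(res.mae * len(y))


def test_loo_no_leakage():
    """Fold i's model is fitted without patient i: its held-out probability
    is reproduced by an independent refit on the other n-1 patients, and
    perturbing x_i moves fold i's prediction only through the test input."""
    rng = np.random.default_rng(47)
    x = rng.normal(0, 1, 10)
    y = (rng.random(10) < 0.5).astype(int)
    y[:2], y[-2:] = 0, 1  # ensure both classes
    spec = ClassifierSpec(method="logistic", l2=0.1)
    res = loo_evaluate(x, y, spec=spec)
    i = 4
    mask = np.arange(10) != i
    model = fit_logistic(x[mask], y[mask], l2=0.1)
    assert res.table["probability"][i] == pytest.approx(
        model.predict_proba(x[i : i + 1])[0], abs=1e-9
    )
    x2 = x.copy()
    x2[i] += 10.0
    res2 = loo_evaluate(x2, y, spec=spec)
    assert res2.table["probability"][i] == pytest.approx(
        model.predict_proba(x2[i : i + 1])[0], abs=1e-9
    )


def test_loo_separated_feature_accuracy_in_most_seeds():
    """Widely separated features give (near-)perfect LOO accuracy.

    With unit-SD groups a patient lands on the wrong side of the midpoint
    with probability Phi(-d/2), so at n = 15 a perfect LOO run needs the
    essentially non-overlapping regime: at d = 6 the error is 0 in at
    least 95% of cohorts, while at d = 3 (where ~65% of cohorts contain
    at least one crosser) the mean error stays near Phi(-1.5).
    """
    from scipy.stats import norm

    seeds = 40
    hits_d6 = 0
    maes_d3 = []
    for s in range(seeds):
        rng = np.random.default_rng(1000 + s)
        y = np.array([0] * 8 + [1] * 7)
        x6 = np.concatenate([rng.normal(0, 1, 8), rng.normal(6, 1, 7)])
        hits_d6 += loo_evaluate(x6, y, spec=ClassifierSpec(method="logistic")).mae == 0
        x3 = np.concatenate([rng.normal(0, 1, 8), rng.normal(3, 1, 7)])
        maes_d3.append(loo_evaluate(x3, y, spec=ClassifierSpec(method="logistic")).mae)
    assert hits_d6 >= int(0.95 * seeds)
    # mean LOO error at d=3 near the midpoint-crossing rate Phi(-1.5)=0.067,
    # below twice that once the LOO boundary's sampling noise is allowed for
    assert np.mean(maes_d3) < 2 * norm.cdf(-1.5)


def test_loo_requires_three_patients_and_two_classes():
    with pytest.raises(ValidationError):
        loo_evaluate([1.0, 2.0], [0, 1])
    with pytest.raises(ValidationError):
        loo_evaluate([1.0, 2.0, 3.0], [1, 1, 1])


def test_loo_degenerate_fold_flagged():
    # one positive: its fold trains on a single class
    x = np.array([0.0, 0.1, 0.2, 5.0])
    y = np.array([0, 0, 0, 1])
    res = loo_evaluate(x, y, ["a", "b", "c", "d"], ClassifierSpec(l2=1e-2))
    assert res.degenerate_folds == ["d"]
    assert res.table["probability"][3] == 0.0  # majority (all-0) training fold
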