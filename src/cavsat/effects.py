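"""Counterfactual treatment-effect estimation on matched datasets.

The T-learner fits one random-forest outcome model per arm, predicts both
potential outcomes (y1, y0) for every matched record, and reports the
individual treatment effect ITE = y1 − y0.  ATE/ATT/ATC are averages of the
ITE over everyone / the treated / the controls, so the decomposition
``ate = (n_t·att + n_c·atc) / n`` holds exactly.  The double-residual
estimator regresses out-of-fold residuals of the outcome on residuals of
the treatment (both predicted from the baseline covariates) as an
orthogonalized cross-check.  Per-method estimates are combined with the
ensemble weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import StratifiedKFold, cross_val_predict


@dataclass(frozen=True)
class ITEVector:
    y1_hat: np.ndarray
    y0_hat: np.ndarray
    ite: np.ndarray
    arm: np.ndarray  # 0/1

    def __post_init__(self):
        if not np.allclose(self.ite, self.y1_hat - self.y0_hat):
            raise ValueError("ite must equal y1_hat - y0_hat")


@dataclass(frozen=True)
class EffectTriple:
    ate: float
    att: float
    atc: float


class TLearner(BaseEstimator):
    """Per-arm random-forest outcome models for counterfactual prediction.

    Defaults: 500 trees, unlimited depth, sqrt(p) features per split; one
    fixed seed per arm derived from ``random_state``.
    """

    def __init__(self, n_estimators: int = 500, random_state: int = 0, min_arm_size: int = 10):
        self.n_estimators = n_estimators
        self.random_state = random_state
        self.min_arm_size = min_arm_size

    def fit(self, X, t, y):
        X = np.asarray(X, dtype=float)
        t = np.asarray(t, dtype=int)
        y = np.asarray(y, dtype=float)
        if not np.isfinite(X).all() or not np.isfinite(y).all():
            raise ValueError("covariates and outcome must be finite")
        for arm, label in ((1, "treated"), (0, "control")):
            if (t == arm).sum() < self.min_arm_size:
                raise ValueError(f"{label} arm has fewer than {self.min_arm_size} records")
        # training rows sorted canonically so predictions are invariant to
        # the record order of the input (bootstrap draws depend on row order)
        def _canonical(mask):
            Xa, ya = X[mask], y[mask]
            order = np.lexsort(tuple(Xa.T) + (ya,))
            return Xa[order], ya[order]

        self.model_treated_ = RandomForestRegressor(
            n_estimators=self.n_estimators, max_features="sqrt",
            random_state=self.random_state, n_jobs=1,
        ).fit(*_canonical(t == 1))
        self.model_control_ = RandomForestRegressor(
            n_estimators=self.n_estimators, max_features="sqrt",
            random_state=self.random_state + 1, n_jobs=1,
        ).fit(*_canonical(t == 0))
        self.arm_ = t
        y1 = self.model_treated_.predict(X)
        y0 = self.model_control_.predict(X)
        self.ite_vector_ = ITEVector(y1_hat=y1, y0_hat=y0, ite=y1 - y0, arm=t)
        return self

    def predict_ite(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.model_treated_.predict(X) - self.model_control_.predict(X)

    @property
    def feature_importances_(self) -> np.ndarray:
        imp = 0.5 * (self.model_treated_.feature_importances_ + self.model_control_.feature_importances_)
        total = imp.sum()
        return imp / total if total > 0 else np.full_like(imp, 1.0 / imp.size)


def t_learner(X, t, y, seed: int = 0, n_estimators: int = 500) -> ITEVector:
    """Fit the T-learner and return its ITE vector (functional wrapper)."""
    return TLearner(n_estimators=n_estimators, random_state=seed).fit(X, t, y).ite_vector_


def effects(ite: ITEVector) -> EffectTriple:
    """ATE / ATT / ATC as subpopulation means of the ITE."""
    arm = np.asarray(ite.arm, dtype=bool)
    if arm.all() or not arm.any():
        raise ValueError("both arms must be present")
    return EffectTriple(
        ate=float(ite.ite.mean()),
        att=float(ite.ite[arm].mean()),
        atc=float(ite.ite[~arm].mean()),
    )


class DoubleResidualEstimator(BaseEstimator):
    """Residual-on-residual treatment-effect estimate.

    Out-of-fold (k-fold, arm-stratified) random-forest predictions give
    outcome residuals e_y = y − ŷ and treatment residuals e_t = t − t̂
    (t̂ from classifier probabilities); the effect is the least-squares
    slope of e_y on e_t, through the origin by default.
    """

    def __init__(self, k: int = 5, n_estimators: int = 200, random_state: int = 0, fit_intercept: bool = False):
        self.k = k
        self.n_estimators = n_estimators
        self.random_state = random_state
        self.fit_intercept = fit_intercept

    def fit(self, X, t, y):
        X = np.asarray(X, dtype=float)
        t = np.asarray(t, dtype=int)
        y = np.asarray(y, dtype=float)
        for arm, label in ((1, "treated"), (0, "control")):
            if (t == arm).sum() < self.k:
                raise ValueError(f"{label} arm too small for {self.k}-fold residualization")
        cv = StratifiedKFold(n_splits=self.k, shuffle=True, random_state=self.random_state)
        y_hat = cross_val_predict(
            RandomForestRegressor(
                n_estimators=self.n_estimators, max_features="sqrt",
                random_state=self.random_state, n_jobs=1,
            ),
            X, y, cv=list(cv.split(X, t)),
        )
        t_hat = cross_val_predict(
            RandomForestClassifier(
                n_estimators=self.n_estimators, max_features="sqrt",
                random_state=self.random_state + 1, n_jobs=1,
            ),
            X, t, cv=list(cv.split(X, t)), method="predict_proba",
        )[:, 1]
        e_y = y - y_hat
        e_t = t - t_hat
        denom = float((e_t**2).sum())
        if denom < 1e-12:
            raise ValueError("no residual treatment variation")
        if self.fit_intercept:
            e_t_c = e_t - e_t.mean()
            self.effect_ = float((e_y * e_t_c).sum() / (e_t_c**2).sum())
        else:
            self.effect_ = float((e_y * e_t).sum() / denom)
        self.residuals_y_ = e_y
        self.residuals_t_ = e_t
        return self


def double_residual(X, t, y, seed: int = 0, k: int = 5, n_estimators: int = 200) -> float:
    return DoubleResidualEstimator(k=k, n_estimators=n_estimators, random_state=seed).fit(X, t, y).effect_


def variable_importance(X: pd.DataFrame, t, y, seed: int = 0, n_estimators: int = 500) -> pd.Series:
    """Impurity importances averaged over the two arm forests, normalized."""
    learner = TLearner(n_estimators=n_estimators, random_state=seed).fit(X, t, y)
    return pd.Series(learner.feature_importances_, index=list(pd.DataFrame(X).columns))


def weighted_aggregate(per_method: dict[str, float], weights: dict[str, float]) -> float:
    """Ensemble-weighted average of per-method estimates (Σ w_m · v_m)."""
    if set(per_method) != set(weights):
        raise ValueError(
            f"method sets differ: {sorted(per_method)} vs {sorted(weights)}"
        )
    return float(sum(weights[m] * per_method[m] for m in per_method))
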