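"""Five-dimension quality scoring of matched datasets and ensemble weights.

Each matching method is scored on: mean SMD balance (25%), max SMD balance
(15%), predictive performance = average five-fold cross-validated R² of
random-forest outcome models (25%), Rosenbaum robustness = fraction of
outcomes still significant at Γ = 1.5 (30%), and treated-arm sample
retention (5%).  Per dimension every method receives its share of the
cross-method total (inverse shares for the SMD dimensions, so better
balance means more weight); the convex combination of shares is then
renormalized into ensemble weights that sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import StratifiedKFold

from .outcomes import OUTCOME_METRICS
from .sensitivity import DEFAULT_DIRECTIONS, wilcoxon_bounds

#: The five dimension weights (mean SMD, max SMD, CV-R², robustness, retention).
DEFAULT_DIMENSION_WEIGHTS: tuple[float, ...] = (0.25, 0.15, 0.25, 0.30, 0.05)


@dataclass(frozen=True)
class MethodQuality:
    """Quality profile of one matched dataset."""

    mean_smd: float
    max_smd: float
    cv_r2: dict[str, float]
    cv_r2_average: float
    robustness: float
    retention: float

    def __post_init__(self):
        if not 0.0 <= self.robustness <= 1.0:
            raise ValueError("robustness must be in [0, 1]")
        if not 0.0 < self.retention <= 1.0:
            raise ValueError("retention must be in (0, 1]")


def cv_r2(
    X: pd.DataFrame,
    t: np.ndarray,
    outcomes: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    n_estimators: int = 200,
) -> dict[str, float]:
    """Out-of-fold R² of a random-forest model per outcome on a matched sample.

    The design matrix is the covariates plus the arm indicator; folds are
    stratified by arm.  R² = 1 − SSE/SST over pooled out-of-fold
    predictions; negative values are retained.  A constant outcome scores 0
    with a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    t = np.asarray(t, dtype=int)
    if len(t) < 2 * k:
        raise ValueError(f"matched sample size {len(t)} too small for {k}-fold CV")
    design = np.column_stack([X.to_numpy(dtype=float), t])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(design, t))
    out: dict[str, float] = {}
    for col in outcomes.columns:
        y = outcomes[col].to_numpy(dtype=float)
        sst = float(((y - y.mean()) ** 2).sum())
        if sst == 0.0:
            warnings.warn(f"constant outcome {col!r}; R² reported as 0")
            out[col] = 0.0
            continue
        pred = np.empty_like(y)
        for f, (tr, te) in enumerate(folds):
            rf = RandomForestRegressor(
                n_estimators=n_estimators, max_features="sqrt", random_state=seed + f, n_jobs=1
            )
            rf.fit(design[tr], y[tr])
            pred[te] = rf.predict(design[te])
        out[col] = float(1.0 - ((y - pred) ** 2).sum() / sst)
    return out


def rosenbaum_robustness(
    pair_diffs_by_outcome: dict[str, np.ndarray],
    gamma: float = 1.5,
    alpha: float = 0.05,
    directions: dict[str, int] | None = None,
) -> float:
    """Fraction of outcomes whose Γ-bounded signed-rank test stays significant.

    The upper-bound p-value is used: an outcome counts as robust only when
    even the most adverse hidden bias of magnitude Γ leaves p < alpha.
    Directionless outcomes are tested two-sided (doubled smaller one-sided
    upper bound).
    """
    if gamma < 1.0:
        raise ValueError("gamma must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    directions = {**DEFAULT_DIRECTIONS, **(directions or {})}
    n_sig = 0
    for outcome, d in pair_diffs_by_outcome.items():
        d = np.asarray(d, dtype=float)
        if np.count_nonzero(d) < 5:
            raise ValueError(f"outcome {outcome!r}: fewer than 5 nonzero pair differences")
        sign = directions.get(outcome, 0)
        if sign == 0:
            p = min(1.0, 2.0 * min(wilcoxon_bounds(d, gamma)[1], wilcoxon_bounds(-d, gamma)[1]))
        else:
            p = wilcoxon_bounds(sign * d, gamma)[1]
        if p < alpha:
            n_sig += 1
    return n_sig / len(pair_diffs_by_outcome)


def _share(values: np.ndarray) -> np.ndarray:
    total = values.sum()
    if total <= 0.0:
        return np.full(values.shape, 1.0 / values.size)
    return values / total


def composite_weight(
    qualities: dict[str, MethodQuality],
    dimension_weights: tuple[float, ...] = DEFAULT_DIMENSION_WEIGHTS,
    eps: float = 1e-6,
) -> dict[str, float]:
    """Normalized ensemble weights from per-method quality profiles.

    Balance dimensions use inverse-SMD shares ``1/(smd+ε)``; CV-R² averages
    are floored at zero before normalization (all-zero → equal shares);
    robustness and retention are normalized as-is.  The composite is the
    dimension-weighted sum of shares, renormalized to sum to one.
    """
    if len(qualities) == 0:
        raise ValueError("no methods")
    if abs(sum(dimension_weights) - 1.0) > 1e-9:
        raise ValueError("dimension weights must sum to 1")
    methods = list(qualities)
    if len(methods) == 1:
        return {methods[0]: 1.0}
    q = [qualities[m] for m in methods]
    s_mean = _share(np.array([1.0 / (x.mean_smd + eps) for x in q]))
    s_max = _share(np.array([1.0 / (x.max_smd + eps) for x in q]))
    s_r2 = _share(np.array([max(0.0, x.cv_r2_average) for x in q]))
    s_rob = _share(np.array([x.robustness for x in q]))
    s_ret = _share(np.array([x.retention for x in q]))
    w = dimension_weights
    raw = w[0] * s_mean + w[1] * s_max + w[2] * s_r2 + w[3] * s_rob + w[4] * s_ret
    final = _share(raw)
    return dict(zip(methods, final.tolist()))
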