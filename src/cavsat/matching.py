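"""Propensity model, SMD balance diagnostics and four 1:1 matching algorithms.

All matchers follow the scikit-learn estimator convention: construct with
hyperparameters, ``fit(X, t)`` with a numeric covariate frame and a 0/1
treatment indicator, then read fitted attributes (``pairs_`` as positional
``(treated_index, control_index)`` tuples, ``retained_n_``).  Matching is
always 1:1 without replacement.

Methods:

- :class:`NearestCaliperMatcher` — greedy nearest-neighbour on the logit
  propensity score within a caliper, hardest-to-match (highest PS) treated
  first; unmatched treated are dropped.
- :class:`MahalanobisMatcher` — global greedy on Mahalanobis distance with
  pooled within-arm covariance on standardized covariates.
- :class:`OptimalExactMatcher` — exact assignment (Hungarian) minimising
  total |logit PS| distance within strata of the exact variables.
- :class:`GeneticMatcher` — evolutionary search over diagonal covariate
  weights of a generalized distance, scored by post-match balance
  (minimise max SMD, tie-break mean SMD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from scipy.special import logit
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression


# ---------------------------------------------------------------------------
# balance


def smd(values_t, values_c, kind: str = "continuous") -> float:
    """Absolute standardized mean difference between two groups.

    continuous: |m_t − m_c| / sqrt((s²_t + s²_c)/2), sample variances;
    binary:     |p_t − p_c| / sqrt((p_t(1−p_t) + p_c(1−p_c))/2).
    Zero pooled SD returns 0 for equal means, +inf (with a warning) otherwise.
    """
    vt = np.asarray(values_t, dtype=float)
    vc = np.asarray(values_c, dtype=float)
    if vt.size == 0 or vc.size == 0:
        raise ValueError("both groups must be nonempty")
    if kind == "binary":
        if not (np.isin(vt, (0.0, 1.0)).all() and np.isin(vc, (0.0, 1.0)).all()):
            raise ValueError("binary SMD requires values in {0, 1}")
        pt, pc = vt.mean(), vc.mean()
        pooled = np.sqrt((pt * (1 - pt) + pc * (1 - pc)) / 2.0)
        diff = abs(pt - pc)
    elif kind == "continuous":
        pooled = np.sqrt((vt.var(ddof=1) + vc.var(ddof=1)) / 2.0)
        diff = abs(vt.mean() - vc.mean())
    else:
        raise ValueError(f"unknown kind {kind!r}")
    if pooled == 0.0:
        if diff == 0.0:
            return 0.0
        warnings.warn("zero pooled SD with unequal means; SMD reported as inf")
        return float("inf")
    return float(diff / pooled)


def _is_binary(x: np.ndarray) -> bool:
    return np.isin(x, (0.0, 1.0)).all()


def standardized_mean_differences(X: pd.DataFrame, t: np.ndarray) -> pd.Series:
    """Per-covariate absolute SMD between arms (binary auto-detected)."""
    t = np.asarray(t, dtype=bool)
    out = {}
    for c in X.columns:
        x = X[c].to_numpy(dtype=float)
        kind = "binary" if _is_binary(x) else "continuous"
        out[c] = smd(x[t], x[~t], kind=kind)
    return pd.Series(out)


@dataclass(frozen=True)
class BalanceTable:
    """Per-covariate SMD before and after matching, with summaries."""

    table: pd.DataFrame  # columns: smd_before, smd_after
    mean_smd: float
    max_smd: float
    mean_smd_before: float
    max_smd_before: float


def balance_report(X: pd.DataFrame, t: np.ndarray, pairs: list[tuple[int, int]]) -> BalanceTable:
    """Balance diagnostics for a matched dataset against the full cohort."""
    t = np.asarray(t, dtype=bool)
    before = standardized_mean_differences(X, t)
    ti = np.array([p[0] for p in pairs], dtype=int)
    ci = np.array([p[1] for p in pairs], dtype=int)
    after = {}
    for c in X.columns:
        x = X[c].to_numpy(dtype=float)
        kind = "binary" if _is_binary(x) else "continuous"
        after[c] = smd(x[ti], x[ci], kind=kind)
    after = pd.Series(after)
    table = pd.DataFrame({"smd_before": before, "smd_after": after})
    finite = after[np.isfinite(after)]
    return BalanceTable(
        table=table,
        mean_smd=float(finite.mean()),
        max_smd=float(finite.max()),
        mean_smd_before=float(before[np.isfinite(before)].mean()),
        max_smd_before=float(before[np.isfinite(before)].max()),
    )


# ---------------------------------------------------------------------------
# propensity model


class PropensityModel(BaseEstimator):
    """Main-effects logistic propensity model.

    Continuous covariates are z-scored; binary (0/1) columns enter raw.
    Constant columns are dropped with a warning; perfect separation triggers
    a ridge-stabilized (L2) refit with a warning.  Fitted attributes:
    ``coef_`` (dict, slopes on the standardized scale), ``intercept_``,
    ``scores_`` (propensities strictly inside (0,1)), ``logit_scores_``.
    """

    def __init__(self, ridge_C: float = 1.0, max_iter: int = 2000):
        self.ridge_C = ridge_C
        self.max_iter = max_iter

    def fit(self, X: pd.DataFrame, t):
        t = np.asarray(t, dtype=int)
        if len(np.unique(t)) < 2:
            raise ValueError("both arms must be present")
        X = pd.DataFrame(X)
        if not np.isfinite(X.to_numpy(dtype=float)).all():
            raise ValueError("covariates must be finite")
        keep, means, sds = [], {}, {}
        for c in X.columns:
            x = X[c].to_numpy(dtype=float)
            if x.std(ddof=0) == 0.0:
                warnings.warn(f"constant covariate {c!r} dropped from propensity model")
                continue
            keep.append(c)
            if _is_binary(x):
                means[c], sds[c] = 0.0, 1.0
            else:
                means[c], sds[c] = float(x.mean()), float(x.std(ddof=0))
        self.columns_ = keep
        self.means_, self.sds_ = means, sds
        Z = self._standardize(X)
        if Z.shape[1] == 0:
            p = t.mean()
            self.intercept_ = float(logit(p))
            self.coef_ = {}
            self.scores_ = np.full(len(t), p)
        else:
            model = LogisticRegression(penalty=None, solver="lbfgs", max_iter=self.max_iter)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(Z, t)
            p = model.predict_proba(Z)[:, 1]
            eps = 1e-8
            if np.abs(model.coef_).max() > 30.0 or p.min() < eps or p.max() > 1 - eps:
                warnings.warn("perfect separation detected; ridge-stabilized refit")
                model = LogisticRegression(C=self.ridge_C, solver="lbfgs", max_iter=self.max_iter)
                model.fit(Z, t)
                p = model.predict_proba(Z)[:, 1]
            self.intercept_ = float(model.intercept_[0])
            self.coef_ = dict(zip(keep, model.coef_[0]))
            self.scores_ = p
        self.scores_ = np.clip(self.scores_, 1e-12, 1 - 1e-12)
        self.logit_scores_ = logit(self.scores_)
        self.t_ = t
        return self

    def _standardize(self, X: pd.DataFrame) -> np.ndarray:
        cols = [
            (X[c].to_numpy(dtype=float) - self.means_[c]) / self.sds_[c] for c in self.columns_
        ]
        return np.column_stack(cols) if cols else np.empty((len(X), 0))


def fit_propensity(cohort_X: pd.DataFrame, t) -> PropensityModel:
    """Fit the logistic propensity model (functional wrapper)."""
    return PropensityModel().fit(cohort_X, t)


# ---------------------------------------------------------------------------
# matched dataset container


@dataclass(frozen=True)
class MatchedDataset:
    """1:1 matched pairs: positional indices into the cohort used to fit."""

    method: str
    pairs: tuple[tuple[int, int], ...]
    retained_n: int

    def __post_init__(self):
        ts = [p[0] for p in self.pairs]
        cs = [p[1] for p in self.pairs]
        if len(set(ts)) != len(ts) or len(set(cs)) != len(cs) or set(ts) & set(cs):
            raise ValueError("pairs must be disjoint 1:1 without replacement")

    @property
    def treated_indices(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs], dtype=int)

    @property
    def control_indices(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=int)

    @property
    def all_indices(self) -> np.ndarray:
        return np.concatenate([self.treated_indices, self.control_indices])


# ---------------------------------------------------------------------------
# greedy primitives


def greedy_match_global(dist: np.ndarray) -> list[tuple[int, int]]:
    """Global greedy 1:1: repeatedly take the smallest available distance.

    Ties break on (treated row, control column) order for determinism.
    Indices are matrix-local.
    """
    n_t, n_c = dist.shape
    order = np.lexsort(
        (np.tile(np.arange(n_c), n_t), np.repeat(np.arange(n_t), n_c), dist.ravel())
    )
    t_used = np.zeros(n_t, dtype=bool)
    c_used = np.zeros(n_c, dtype=bool)
    pairs = []
    n_pairs = min(n_t, n_c)
    for k in order:
        i, j = divmod(int(k), n_c)
        if not t_used[i] and not c_used[j]:
            t_used[i] = c_used[j] = True
            pairs.append((i, j))
            if len(pairs) == n_pairs:
                break
    return pairs


def greedy_match_by_order(
    dist: np.ndarray, treated_order: np.ndarray, caliper: float | None = None
) -> list[tuple[int, int]]:
    """Sequential greedy: each treated (in given order) takes its nearest
    available control, skipped if the nearest exceeds the caliper.

    Ties on distance break on the lower control column.
    """
    n_t, n_c = dist.shape
    c_used = np.zeros(n_c, dtype=bool)
    pairs = []
    for i in treated_order:
        avail = ~c_used
        if not avail.any():
            break
        d = np.where(avail, dist[i], np.inf)
        j = int(np.argmin(d))  # argmin takes the first (lowest column) on ties
        if caliper is not None and d[j] > caliper:
            continue
        c_used[j] = True
        pairs.append((int(i), j))
    return pairs


# ---------------------------------------------------------------------------
# matchers


class _BaseMatcher(BaseEstimator):
    method: str = "base"

    def _split(self, X: pd.DataFrame, t):
        t = np.asarray(t, dtype=int)
        if set(np.unique(t)) - {0, 1}:
            raise ValueError("t must be 0/1")
        ti = np.flatnonzero(t == 1)
        ci = np.flatnonzero(t == 0)
        if ti.size == 0 or ci.size == 0:
            raise ValueError("both arms must be present")
        return pd.DataFrame(X), t, ti, ci

    def _finish(self, local_pairs, ti, ci) -> MatchedDataset:
        pairs = tuple((int(ti[i]), int(ci[j])) for i, j in local_pairs)
        md = MatchedDataset(method=self.method, pairs=pairs, retained_n=len(pairs))
        self.pairs_ = md.pairs
        self.retained_n_ = md.retained_n
        self.matched_ = md
        return md


class NearestCaliperMatcher(_BaseMatcher):
    """Greedy nearest-neighbour caliper matching on the logit propensity.

    The caliper is ``caliper_sd`` times the pooled (within-arm averaged) SD
    of the logit scores; treated units are processed in descending
    propensity order and dropped when no control lies inside the caliper.
    """

    method = "nearest_caliper"

    def __init__(self, caliper_sd: float = 0.2):
        self.caliper_sd = caliper_sd

    def fit(self, X, t, propensity: PropensityModel | None = None):
        if self.caliper_sd <= 0:
            raise ValueError("caliper_sd must be > 0")
        X, t, ti, ci = self._split(X, t)
        model = propensity if propensity is not None else PropensityModel().fit(X, t)
        self.propensity_ = model
        lt = model.logit_scores_[ti]
        lc = model.logit_scores_[ci]
        pooled_sd = np.sqrt((lt.var(ddof=1) + lc.var(ddof=1)) / 2.0) if min(lt.size, lc.size) > 1 else np.std(model.logit_scores_, ddof=1)
        self.caliper_ = float(self.caliper_sd * pooled_sd)
        dist = np.abs(lt[:, None] - lc[None, :])
        order = np.argsort(-lt, kind="stable")
        local = greedy_match_by_order(dist, order, caliper=self.caliper_)
        if not local:
            raise ValueError("no treated unit could be matched within the caliper")
        self._finish(sorted(local), ti, ci)
        return self


class MahalanobisMatcher(_BaseMatcher):
    """Global greedy 1:1 on Mahalanobis distance over standardized covariates.

    The metric uses the pooled within-arm covariance; a ridge is added when
    it is numerically singular.  ``diagonal=True`` replaces the metric with
    plain Euclidean distance on the standardized covariates.
    """

    method = "mahalanobis"

    def __init__(self, diagonal: bool = False, ridge: float = 1e-8):
        self.diagonal = diagonal
        self.ridge = ridge

    def fit(self, X, t):
        X, t, ti, ci = self._split(X, t)
        M = X.to_numpy(dtype=float)
        mu = M.mean(axis=0)
        sd = M.std(axis=0, ddof=0)
        sd[sd == 0.0] = 1.0
        Z = (M - mu) / sd
        if self.diagonal:
            dist = cdist(Z[ti], Z[ci], metric="euclidean")
        else:
            S_t = np.cov(Z[ti], rowvar=False) if ti.size > 1 else np.zeros((Z.shape[1],) * 2)
            S_c = np.cov(Z[ci], rowvar=False) if ci.size > 1 else np.zeros((Z.shape[1],) * 2)
            n_t, n_c = ti.size, ci.size
            S = ((n_t - 1) * S_t + (n_c - 1) * S_c) / max(n_t + n_c - 2, 1)
            S = np.atleast_2d(S)
            try:
                VI = np.linalg.inv(S)
            except np.linalg.LinAlgError:
                S = S + self.ridge * np.eye(S.shape[0])
                try:
                    VI = np.linalg.inv(S)
                except np.linalg.LinAlgError:
                    bad = [X.columns[k] for k in range(S.shape[0]) if S[k, k] < 1e-12]
                    raise ValueError(f"singular covariance after regularization; collinear covariates: {bad}")
            cond = np.linalg.cond(S)
            if cond > 1e12:
                S = S + self.ridge * np.eye(S.shape[0])
                if np.linalg.cond(S) > 1e14:
                    ev = np.linalg.eigvalsh(S)
                    bad = [str(c) for c in X.columns]
                    raise ValueError(
                        f"singular covariance after regularization (min eigenvalue {ev.min():.2e}); "
                        f"check for collinear covariates among {bad}"
                    )
                VI = np.linalg.inv(S)
            dist = cdist(Z[ti], Z[ci], metric="mahalanobis", VI=VI)
        local = greedy_match_global(dist)
        self._finish(sorted(local), ti, ci)
        return self


class OptimalExactMatcher(_BaseMatcher):
    """Optimal (assignment-problem) matching on |logit PS| within exact strata.

    Within every level combination of ``exact`` the pairing minimising the
    total logit-propensity distance is solved exactly; a stratum with fewer
    controls than treated is relaxed (its treated units are matched in a
    final unconstrained assignment over leftover controls) with a warning.
    """

    method = "optimal_exact"

    def __init__(self, exact: tuple[str, ...] = ("gender",)):
        self.exact = tuple(exact)

    def fit(self, X, t, propensity: PropensityModel | None = None):
        X, t, ti, ci = self._split(X, t)
        model = propensity if propensity is not None else PropensityModel().fit(X, t)
        self.propensity_ = model
        ls = model.logit_scores_
        missing = [v for v in self.exact if v not in X.columns]
        if missing:
            raise ValueError(f"exact variables not in covariates: {missing}")
        if self.exact:
            strata = X[list(self.exact)].astype(float).apply(tuple, axis=1).to_numpy()
        else:
            strata = np.array([("all",)] * len(X), dtype=object)
        local_pairs: list[tuple[int, int]] = []
        c_used = np.zeros(ci.size, dtype=bool)
        relaxed_t: list[int] = []
        for level in sorted({strata[k] for k in ti}, key=repr):
            t_loc = np.array([k for k in range(ti.size) if strata[ti[k]] == level], dtype=int)
            c_loc = np.array([k for k in range(ci.size) if strata[ci[k]] == level and not c_used[k]], dtype=int)
            if c_loc.size < t_loc.size:
                warnings.warn(
                    f"stratum {level!r} has {c_loc.size} controls for {t_loc.size} treated; relaxed"
                )
                relaxed_t.extend(t_loc.tolist())
                continue
            D = np.abs(ls[ti[t_loc]][:, None] - ls[ci[c_loc]][None, :])
            r, c = linear_sum_assignment(D)
            for a, b in zip(r, c):
                local_pairs.append((int(t_loc[a]), int(c_loc[b])))
                c_used[c_loc[b]] = True
        if relaxed_t:
            c_free = np.flatnonzero(~c_used)
            if c_free.size < len(relaxed_t):
                raise ValueError("infeasible matching: fewer controls than treated after relaxation")
            D = np.abs(ls[ti[relaxed_t]][:, None] - ls[ci[c_free]][None, :])
            r, c = linear_sum_assignment(D)
            for a, b in zip(r, c):
                local_pairs.append((int(relaxed_t[a]), int(c_free[b])))
        self._finish(sorted(local_pairs), ti, ci)
        return self


def _weighted_greedy(Z_t: np.ndarray, Z_c: np.ndarray, w: np.ndarray) -> list[tuple[int, int]]:
    dist = cdist(Z_t * np.sqrt(w), Z_c * np.sqrt(w), metric="euclidean")
    return greedy_match_global(dist)


class GeneticMatcher(_BaseMatcher):
    """Evolutionary search over diagonal covariate weights.

    Each candidate positive weight vector ``w`` defines the distance
    ``sqrt(Σ w_j (z_tj − z_cj)²)`` and induces a global-greedy 1:1 match;
    fitness is (max post-match SMD, mean post-match SMD), minimised.  The
    all-ones vector is always in the initial population, so the returned
    match is never worse than the equal-weights match.  Reproducible for a
    given seed.
    """

    method = "genetic"

    def __init__(
        self,
        generations: int = 10,
        pop_size: int = 20,
        seed: int = 0,
        mutation_sd: float = 0.4,
        initial_population: list | None = None,
    ):
        self.generations = generations
        self.pop_size = pop_size
        self.seed = seed
        self.mutation_sd = mutation_sd
        self.initial_population = initial_population

    def fit(self, X, t):
        if self.pop_size < 1 or self.generations < 0:
            raise ValueError("pop_size >= 1 and generations >= 0 required")
        X, t, ti, ci = self._split(X, t)
        M = X.to_numpy(dtype=float)
        mu, sd = M.mean(axis=0), M.std(axis=0, ddof=0)
        sd[sd == 0.0] = 1.0
        Z = (M - mu) / sd
        p = Z.shape[1]
        rng = np.random.default_rng(self.seed)

        def fitness(w: np.ndarray):
            local = _weighted_greedy(Z[ti], Z[ci], w)
            bt = balance_report(X, t, [(int(ti[i]), int(ci[j])) for i, j in local])
            return (bt.max_smd, bt.mean_smd), local

        pop = [np.ones(p)]
        if self.initial_population is not None:
            pop += [np.asarray(w, dtype=float) for w in self.initial_population]
        while len(pop) < self.pop_size:
            pop.append(np.exp(rng.normal(0.0, 0.7, size=p)))
        pop = pop[: max(self.pop_size, len(pop))]

        evaluated = [(fitness(w), w) for w in pop]
        best = min(evaluated, key=lambda e: e[0][0])
        for _ in range(self.generations):
            evaluated.sort(key=lambda e: e[0][0])
            elite = [w for _, w in evaluated[: max(1, len(evaluated) // 2)]]
            children = []
            while len(children) < len(pop) - len(elite):
                a, b = rng.choice(len(elite), size=2, replace=True)
                u = rng.random(p)
                child = elite[a] ** u * elite[b] ** (1 - u)  # geometric crossover
                child = child * np.exp(rng.normal(0.0, self.mutation_sd, size=p))
                children.append(np.clip(child, 1e-6, 1e6))
            evaluated = evaluated[: len(elite)] + [(fitness(w), w) for w in children]
            cand = min(evaluated, key=lambda e: e[0][0])
            if cand[0][0] < best[0][0]:
                best = cand
        (fit_key, local), w = best
        self.fitness_ = fit_key
        self.weights_ = w
        self._finish(sorted(local), ti, ci)
        return self


# ---------------------------------------------------------------------------
# functional wrappers (fixed method registry used by the pipeline)


def match_nearest_caliper(X, t, caliper_sd: float = 0.2, propensity=None) -> MatchedDataset:
    return NearestCaliperMatcher(caliper_sd=caliper_sd).fit(X, t, propensity=propensity).matched_

def match_mahalanobis(X, t, diagonal: bool = False) -> MatchedDataset:
    return MahalanobisMatcher(diagonal=diagonal).fit(X, t).matched_

def match_optimal_exact(X, t, exact=("gender",), propensity=None) -> MatchedDataset:
    return OptimalExactMatcher(exact=exact).fit(X, t, propensity=propensity).matched_

def match_genetic(X, t, generations: int = 10, pop_size: int = 20, seed: int = 0) -> MatchedDataset:
    return GeneticMatcher(generations=generations, pop_size=pop_size, seed=seed).fit(X, t).matched_

MATCHERS = {
    "genetic": match_genetic,
    "mahalanobis": match_mahalanobis,
    "nearest_caliper": match_nearest_caliper,
    "optimal_exact": match_optimal_exact,
}
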