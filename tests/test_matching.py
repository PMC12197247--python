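"""Matching-layer checks: SMD formulas, propensity closed forms, the four
matchers against brute-force oracles, and balance-improvement properties."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from cavsat.cohort import covariate_matrix, treatment_indicator
from cavsat.matching import (
    GeneticMatcher,
    MahalanobisMatcher,
    MatchedDataset,
    NearestCaliperMatcher,
    OptimalExactMatcher,
    PropensityModel,
    balance_report,
    greedy_match_by_order,
    greedy_match_global,
    match_genetic,
    match_mahalanobis,
    match_nearest_caliper,
    match_optimal_exact,
    smd,
    standardized_mean_differences,
)
from cavsat.simulate import CohortParams, generate_cohort


class TestSMD:
    def test_identical_groups_zero(self):
        assert smd([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_unit_separation(self, rng):
        t = rng.normal(1, 1, 20000)
        c = rng.normal(0, 1, 20000)
        assert smd(t, c) == pytest.approx(1.0, abs=0.03)

    def test_hand_computation(self):
        assert smd([1, 2, 3], [2, 3, 4]) == pytest.approx(1.0, rel=1e-12)

    def test_binary_formula(self):
        # p_t=0.6, p_c=0.2: |0.4| / sqrt((0.24+0.16)/2)
        t = [1] * 6 + [0] * 4
        c = [1] * 2 + [0] * 8
        assert smd(t, c, kind="binary") == pytest.approx(0.4 / np.sqrt(0.2), rel=1e-12)

    def test_degenerate_pooled_sd(self):
        assert smd([2.0, 2.0], [2.0, 2.0]) == 0.0
        with pytest.warns(UserWarning):
            assert smd([2.0, 2.0], [3.0, 3.0]) == np.inf


class TestPropensityModel:
    def test_intercept_only_closed_form(self):
        t = np.r_[np.ones(5), np.zeros(15)]
        m = PropensityModel().fit(pd.DataFrame(index=range(20)), t)
        assert np.allclose(m.scores_, 0.25)

    def test_two_by_two_slope_is_log_odds_ratio(self):
        x = np.r_[np.ones(30), np.zeros(20), np.ones(10), np.zeros(40)]
        t = np.r_[np.ones(50), np.zeros(50)]
        m = PropensityModel().fit(pd.DataFrame({"x": x}), t)
        assert m.coef_["x"] == pytest.approx(np.log(6), abs=1e-4)

    def test_scores_invariant_to_record_order(self, cohort_design):
        X, t = cohort_design
        perm = np.random.default_rng(0).permutation(len(t))
        a = PropensityModel().fit(X, t).scores_
        b = PropensityModel().fit(X.iloc[perm].reset_index(drop=True), t[perm]).scores_
        assert np.abs(a[perm] - b).max() < 1e-8

    def test_constant_covariate_dropped_with_warning(self, cohort_design):
        X, t = cohort_design
        X = X.assign(flat=1.0)
        with pytest.warns(UserWarning, match="constant covariate"):
            m = PropensityModel().fit(X, t)
        assert "flat" not in m.coef_

    def test_perfect_separation_triggers_ridge(self):
        x = np.r_[np.linspace(1, 2, 20), np.linspace(3, 4, 20)]
        t = np.r_[np.zeros(20), np.ones(20)]
        with pytest.warns(UserWarning, match="separation"):
            m = PropensityModel().fit(pd.DataFrame({"x": x}), t)
        assert np.isfinite(m.logit_scores_).all()
        assert (m.scores_ > 0).all() and (m.scores_ < 1).all()


class TestNearestCaliper:
    def test_treated_outside_caliper_dropped(self):
        dist = np.abs(np.array([[0.0]]) - np.array([[0.9, 0.5]]))
        assert greedy_match_by_order(dist, np.array([0]), caliper=0.2) == []

    def test_picks_nearest_inside_caliper(self):
        dist = np.abs(np.array([[0.0]]) - np.array([[0.4, 0.1]]))
        assert greedy_match_by_order(dist, np.array([0]), caliper=0.2) == [(0, 1)]

    def test_caliper_bound_holds_for_every_pair(self, small_cohort):
        X, t = covariate_matrix(small_cohort), treatment_indicator(small_cohort)
        matcher = NearestCaliperMatcher(caliper_sd=0.2).fit(X, t)
        ls = matcher.propensity_.logit_scores_
        for ti, ci in matcher.pairs_:
            assert abs(ls[ti] - ls[ci]) <= matcher.caliper_ + 1e-12

    def test_tight_caliper_drops_treated(self, small_cohort):
        X, t = covariate_matrix(small_cohort), treatment_indicator(small_cohort)
        md = match_nearest_caliper(X, t, caliper_sd=0.05)
        assert md.retained_n < t.sum()

    def test_error_when_nothing_matchable(self):
        X = pd.DataFrame({"x": [0.0, 0.0, 10.0, 10.0, 10.01, 9.99]})
        t = np.array([1, 1, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="caliper"):
            NearestCaliperMatcher(caliper_sd=1e-6).fit(X, t)


class TestMahalanobis:
    def test_one_covariate_reduces_to_nearest_neighbor_on_z(self):
        x = np.array([0.0, 1.0, 5.0, 0.1, 1.2, 5.3, 9.0])
        t = np.array([1, 1, 1, 0, 0, 0, 0])
        md = match_mahalanobis(pd.DataFrame({"x": x}), t)
        assert set(md.pairs) == {(0, 3), (1, 4), (2, 5)}

    def test_identical_rows_matched_first_at_zero_distance(self):
        X = pd.DataFrame({"a": [1.0, 9.0, 1.0, 5.0, 8.0], "b": [2.0, 1.0, 2.0, 5.0, 0.5]})
        t = np.array([1, 1, 0, 0, 0])
        md = match_mahalanobis(X, t)
        assert (0, 2) in md.pairs

    def test_two_by_two_matches_brute_force_greedy(self, rng):
        for _ in range(20):
            Xt, Xc = rng.normal(size=(2, 2)), rng.normal(size=(2, 2))
            X = pd.DataFrame(np.vstack([Xt, Xc]), columns=["a", "b"])
            t = np.array([1, 1, 0, 0])
            md = match_mahalanobis(X, t, diagonal=True)
            mu, sd = X.to_numpy().mean(0), X.to_numpy().std(0)
            Z = (X.to_numpy() - mu) / sd
            D = np.linalg.norm(Z[:2, None, :] - Z[None, 2:, :], axis=2)
            # brute-force global greedy on the 2x2 distance matrix
            flat = sorted(((D[i, j], i, j) for i in range(2) for j in range(2)))
            first = flat[0][1:]
            second = (1 - first[0], 1 - first[1])
            expected = {(first[0], first[1] + 2), (second[0], second[1] + 2)}
            assert set(md.pairs) == expected

    def test_collinear_covariates_raise(self):
        x = np.arange(10, dtype=float)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        t = np.r_[np.ones(5), np.zeros(5)].astype(int)
        with pytest.raises(ValueError, match="collinear|singular"):
            MahalanobisMatcher(ridge=0.0).fit(X, t)


class TestOptimalExact:
    def test_beats_greedy_on_counterexample(self):
        # treated logits {0.4, 0.5}, controls {0.45, 0.0}
        D = np.abs(np.array([[0.4], [0.5]]) - np.array([[0.45, 0.0]]))
        greedy = greedy_match_by_order(D, np.array([0, 1]))
        greedy_total = sum(D[i, j] for i, j in greedy)
        from scipy.optimize import linear_sum_assignment

        r, c = linear_sum_assignment(D)
        assert greedy_total == pytest.approx(0.55)
        assert D[r, c].sum() == pytest.approx(0.45)

    def test_exact_gender_constraint_is_satisfied(self, small_cohort):
        X, t = covariate_matrix(small_cohort), treatment_indicator(small_cohort)
        md = match_optimal_exact(X, t, exact=("gender",))
        g = X["gender"].to_numpy()
        for ti, ci in md.pairs:
            assert g[ti] == g[ci]

    def test_feasible_strata_retain_all_treated(self, small_cohort):
        X, t = covariate_matrix(small_cohort), treatment_indicator(small_cohort)
        md = match_optimal_exact(X, t, exact=("gender",))
        assert md.retained_n == t.sum()

    def test_infeasible_stratum_relaxed_with_warning(self):
        X = pd.DataFrame({"gender": [1.0, 1.0, 0.0, 0.0, 0.0], "x": [1.0, 2.0, 1.1, 2.2, 3.0]})
        t = np.array([1, 1, 0, 0, 0])
        with pytest.warns(UserWarning, match="relaxed"):
            md = OptimalExactMatcher(exact=("gender",)).fit(X, t).matched_
        assert md.retained_n == 2


class TestGenetic:
    def test_degenerate_search_equals_diagonal_mahalanobis(self, small_cohort):
        X, t = covariate_matrix(small_cohort), treatment_indicator(small_cohort)
        gen = GeneticMatcher(generations=0, pop_size=1, seed=0).fit(X, t)
        assert set(gen.pairs_) == set(match_mahalanobis(X, t, diagonal=True).pairs)

    def test_search_never_worse_than_equal_weights(self, small_cohort):
        X, t = covariate_matrix(small_cohort), treatment_indicator(small_cohort)
        equal = GeneticMatcher(generations=0, pop_size=1, seed=0).fit(X, t)
        searched = GeneticMatcher(generations=4, pop_size=8, seed=0).fit(X, t)
        assert searched.fitness_ <= equal.fitness_

    def test_seed_reproducibility(self, small_cohort):
        X, t = covariate_matrix(small_cohort), treatment_indicator(small_cohort)
        a = match_genetic(X, t, generations=2, pop_size=6, seed=5)
        b = match_genetic(X, t, generations=2, pop_size=6, seed=5)
        assert a.pairs == b.pairs

    def test_matches_grid_search_oracle_on_tiny_instance(self, rng):
        Xt = rng.normal(size=(3, 2))
        Xc = rng.normal(size=(5, 2))
        X = pd.DataFrame(np.vstack([Xt, Xc]), columns=["a", "b"])
        t = np.r_[np.ones(3), np.zeros(5)].astype(int)
        grid = [np.array([wa, wb]) for wa in (0.25, 0.5, 1, 2, 4) for wb in (0.25, 0.5, 1, 2, 4)]
        # independent oracle: evaluate every grid weight by greedy + balance
        mu, sd = X.to_numpy().mean(0), X.to_numpy().std(0)
        Z = (X.to_numpy() - mu) / sd
        best = None
        for w in grid:
            D = np.sqrt((((Z[:3, None, :] - Z[None, 3:, :]) ** 2) * w).sum(axis=2))
            pairs = [(i, j + 3) for i, j in greedy_match_global(D)]
            bt = balance_report(X, t, pairs)
            key = (bt.max_smd, bt.mean_smd)
            best = key if best is None or key < best else best
        gen = GeneticMatcher(generations=0, pop_size=len(grid) + 1, initial_population=grid, seed=0).fit(X, t)
        assert gen.fitness_ <= (best[0] + 1e-9, best[1] + 1e-9)


class TestInvariantsAcrossMethods:
    def test_pairs_are_one_to_one_without_replacement(self, small_cohort):
        X, t = covariate_matrix(small_cohort), treatment_indicator(small_cohort)
        for md in (
            match_genetic(X, t, generations=1, pop_size=4, seed=0),
            match_mahalanobis(X, t),
            match_nearest_caliper(X, t),
            match_optimal_exact(X, t),
        ):
            ts, cs = md.treated_indices, md.control_indices
            assert len(set(ts)) == len(ts) and len(set(cs)) == len(cs)
            assert set(ts).isdisjoint(cs)
            assert (t[ts] == 1).all() and (t[cs] == 0).all()
            assert md.retained_n == len(md.pairs)

    def test_duplicate_pair_construction_rejected(self):
        with pytest.raises(ValueError):
            MatchedDataset(method="x", pairs=((0, 1), (0, 2)), retained_n=2)

    def test_matching_improves_mean_smd_on_confounded_replicates(self):
        """Where assignment is confounded (real imbalance to remove),
        post-match mean SMD <= pre-match mean SMD in >=95% of replicates
        for every method."""
        wins = {m: 0 for m in ("genetic", "mahalanobis", "nearest_caliper", "optimal_exact")}
        n_rep = 100
        for seed in range(n_rep):
            df = generate_cohort(CohortParams(n_total=400, seed=1000 + seed))
            X, t = covariate_matrix(df), treatment_indicator(df)
            mds = {
                "genetic": match_genetic(X, t, generations=5, pop_size=10, seed=seed),
                "mahalanobis": match_mahalanobis(X, t),
                "nearest_caliper": match_nearest_caliper(X, t),
                "optimal_exact": match_optimal_exact(X, t),
            }
            for name, md in mds.items():
                bt = balance_report(X, t, list(md.pairs))
                if bt.mean_smd <= bt.mean_smd_before:
                    wins[name] += 1
        for name, w in wins.items():
            assert w >= 0.95 * n_rep, (name, w)


class TestBalanceReport:
    def test_self_match_gives_zero_smds(self, small_cohort):
        X = covariate_matrix(small_cohort)
        t = treatment_indicator(small_cohort)
        ti = np.flatnonzero(t == 1)
        ci = np.flatnonzero(t == 0)[: len(ti)]
        # fixture: controls given exactly the treated covariate rows
        X2 = X.copy()
        X2.iloc[ci] = X.iloc[ti].to_numpy()
        bt = balance_report(X2, t, list(zip(ti, ci)))
        assert (bt.table["smd_after"] == 0).all()

    def test_hand_built_two_pair_fixture(self):
        X = pd.DataFrame({"x": [1.0, 3.0, 2.0, 4.0]})
        t = np.array([1, 1, 0, 0])
        bt = balance_report(X, t, [(0, 2), (1, 3)])
        # means 2 vs 3, variances 2 and 2 -> smd = 1/sqrt(2)
        assert bt.table.loc["x", "smd_after"] == pytest.approx(1 / np.sqrt(2), rel=1e-12)
        assert bt.mean_smd <= bt.max_smd

    def test_mean_never_exceeds_max(self, small_cohort):
        X, t = covariate_matrix(small_cohort), treatment_indicator(small_cohort)
        bt = balance_report(X, t, list(match_mahalanobis(X, t).pairs))
        assert bt.mean_smd <= bt.max_smd


def test_smd_series_detects_binary(small_cohort):
    X, t = covariate_matrix(small_cohort), treatment_indicator(small_cohort)
    s = standardized_mean_differences(X, t)
    assert set(s.index) == set(X.columns)
    assert (s >= 0).all()
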