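"""Matching, ATT, bias adjustment, variance, estimator selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tenurematch as tm
from tenurematch.matchcore import (MatchingInfeasibleError, _matching_matrix,
                                   mahalanobis_distance,
                                   pooled_inverse_covariance)


def random_instance(seed, n_max=200, n_props=8):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(30, n_max))
    df = pd.DataFrame({
        "biome": rng.choice(["dry", "moist"], n),
        "property_id": rng.integers(0, n_props, n),
        "y_loss": rng.integers(0, 2, n),
        "a": rng.normal(0, 1, n),
        "b": rng.normal(0, 2, n),
        "c": rng.normal(1, 0.5, n),
    })
    treated = np.zeros(n, bool)
    treated[rng.choice(n, max(3, n // 5), replace=False)] = True
    lps = pd.Series(rng.normal(0, 1, n), index=df.index)
    return df, treated, lps


def brute_force_pairs(df, treated, covs, metric, lps, different_property):
    """Independent oracle: direct quadratic-form scan over sorted ids."""
    pairs = {}
    for biome in df["biome"].unique():
        sub = df[df["biome"] == biome]
        tsub = sub[treated[sub.index]]
        csub = sub[~treated[sub.index]].sort_index()
        if len(tsub) == 0 or len(csub) == 0:
            continue
        pool = pd.concat([tsub, csub])
        X = _matching_matrix(pool, covs, metric, lps)
        VI = pooled_inverse_covariance(X)
        coords = dict(zip(pool.index, X))
        for ti in tsub.index:
            best = None
            for ci in csub.index:
                if different_property and (df.loc[ci, "property_id"]
                                           == df.loc[ti, "property_id"]):
                    continue
                d = mahalanobis_distance(coords[ti], coords[ci], VI)
                if best is None or d < best[1] - 1e-10:
                    best = (ci, d)
            if best is not None:
                pairs[ti] = best[0]
    return pairs


class TestMahalanobisDistance:
    def test_identity_point(self):
        VI = np.eye(3)
        u = np.array([1.0, 2.0, 3.0])
        assert mahalanobis_distance(u, u, VI) == 0.0

    def test_identity_covariance_is_euclidean(self):
        VI = np.eye(2)
        assert mahalanobis_distance([0, 0], [3, 4], VI) == pytest.approx(5.0)

    def test_diagonal_covariance_hand_value(self):
        # S = diag(4, 1) -> S^-1 = diag(1/4, 1); d((2,0),(0,0)) = 1
        VI = np.linalg.inv(np.diag([4.0, 1.0]))
        assert mahalanobis_distance([2, 0], [0, 0], VI) == pytest.approx(1.0)

    def test_singular_covariance_regularized(self):
        X = np.column_stack([np.arange(10.0), np.arange(10.0)])  # collinear
        VI = pooled_inverse_covariance(X)
        assert np.all(np.isfinite(VI))


class TestNearestNeighbor:
    def test_identical_control_selected_at_zero_distance(self):
        df = pd.DataFrame({
            "biome": ["dry"] * 4,
            "property_id": [0, 1, 2, 3],
            "y_loss": [1, 0, 0, 0],
            "a": [1.0, 1.0, 5.0, -2.0],
            "b": [2.0, 2.0, 0.0, 1.0],
        })
        treated = np.array([True, False, False, False])
        m = tm.match_nearest_neighbor(df, treated, ["a", "b"])
        assert m.control_ids.tolist() == [1]
        assert m.distances[0] == pytest.approx(0.0)

    def test_same_property_zero_distance_control_skipped(self):
        df = pd.DataFrame({
            "biome": ["dry"] * 4,
            "property_id": [7, 7, 1, 2],
            "y_loss": [1, 0, 0, 0],
            "a": [1.0, 1.0, 1.5, -2.0],
            "b": [2.0, 2.0, 2.0, 1.0],
        })
        treated = np.array([True, False, False, False])
        m = tm.match_nearest_neighbor(df, treated, ["a", "b"])
        assert m.control_ids.tolist() == [2]  # next-nearest admissible

    @pytest.mark.parametrize("metric", ["mahalanobis_trimmed",
                                        "ps_augmented"])
    @pytest.mark.parametrize("different_property", [True, False])
    def test_equals_brute_force(self, metric, different_property):
        for seed in range(12):
            df, treated, lps = random_instance(seed)
            m = tm.match_nearest_neighbor(
                df, treated, ["a", "b", "c"], metric=metric, lps=lps,
                different_property=different_property)
            expected = brute_force_pairs(df, treated, ["a", "b", "c"],
                                         metric, lps, different_property)
            assert dict(zip(m.treated_ids, m.control_ids)) == expected

    def test_bookkeeping_monotone_under_constraints(self):
        df, treated, lps = random_instance(99, n_props=3)
        free = tm.match_nearest_neighbor(df, treated, ["a", "b", "c"],
                                         different_property=False)
        constrained = tm.match_nearest_neighbor(df, treated, ["a", "b", "c"],
                                               different_property=True)
        assert len(constrained) <= len(free)
        assert constrained.n_matched_controls <= (~treated).sum()

    def test_reuse_counts_sum_to_pairs(self):
        df, treated, lps = random_instance(3)
        m = tm.match_nearest_neighbor(df, treated, ["a", "b", "c"])
        assert m.reuse_counts.sum() == len(m)


class TestRawATT:
    def test_all_zero_pairs(self):
        m = tm.MatchedSample(np.arange(3), np.arange(3) + 10,
                             np.zeros(3), np.zeros(3), "mahalanobis_trimmed",
                             "dry")
        assert tm.raw_att(m) == 0.0

    def test_hand_pairs(self):
        # (1-0, 0-1, 0-0) -> mean 0
        m = tm.MatchedSample(np.arange(3), np.arange(3) + 10, np.zeros(3),
                             np.array([1.0, -1.0, 0.0]),
                             "mahalanobis_trimmed", "dry")
        assert tm.raw_att(m) == 0.0

    def test_group_mean_difference(self):
        # treated mean 0.04 vs control mean 0.08 -> ATT -0.04
        tt = np.r_[np.full(4, 1.0) - 0.0, np.zeros(96)] - \
            np.r_[np.full(8, 1.0), np.zeros(92)]
        m = tm.MatchedSample(np.arange(100), np.arange(100) + 500,
                             np.zeros(100), tt, "mahalanobis_trimmed", "dry")
        assert tm.raw_att(m) == pytest.approx(-0.04)

    def test_empty_raises(self):
        m = tm.MatchedSample(np.array([]), np.array([]), np.array([]),
                             np.array([]), "mahalanobis_trimmed", "dry")
        with pytest.raises(ValueError):
            tm.raw_att(m)


class TestBiasAdjust:
    def test_exact_matches_leave_att_unchanged(self):
        rng = np.random.default_rng(0)
        n = 40
        X = rng.normal(0, 1, (n, 2))
        df = pd.DataFrame(np.vstack([X, X]), columns=["a", "b"])
        df["y_loss"] = rng.integers(0, 2, 2 * n).astype(float)
        m = tm.match_nearest_neighbor(
            df.assign(biome="dry", property_id=np.r_[np.zeros(n),
                                                     np.ones(n)]),
            np.r_[np.ones(n, bool), np.zeros(n, bool)], ["a", "b"])
        assert np.allclose(m.distances, 0)
        adj, tt_adj = tm.bias_adjust(m, df, ["a", "b"])
        assert adj == pytest.approx(tm.raw_att(m))
        assert np.allclose(tt_adj, m.tt)

    def test_adjustment_reduces_confounding_bias(self):
        # continuous outcome linear in x, treated shifted in x, coarse
        # matching from a thin control pool: the regression correction
        # should land nearer the true null effect than the raw ATT
        wins = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            n_t, n_c = 40, 30
            x_t = rng.normal(1.2, 1, n_t)
            x_c = rng.normal(0.0, 0.7, n_c)
            df = pd.DataFrame({
                "biome": "dry",
                "property_id": np.r_[np.zeros(n_t), np.ones(n_c)],
                "x": np.r_[x_t, x_c],
            })
            df["y_loss"] = 1.0 * df["x"] + rng.normal(0, 0.05, n_t + n_c)
            treated = np.r_[np.ones(n_t, bool), np.zeros(n_c, bool)]
            m = tm.match_nearest_neighbor(df, treated, ["x"])
            raw = tm.raw_att(m)
            adj, _ = tm.bias_adjust(m, df, ["x"])
            if abs(adj) < abs(raw):
                wins += 1
        assert wins >= 0.9 * reps

    def test_adjustment_can_reveal_significance(self):
        # qualitative pattern: a raw estimate straddling zero becomes a
        # clearly negative adjusted one once covariate gaps are removed
        rng = np.random.default_rng(7)
        n_t, n_c = 120, 150
        x_t = rng.normal(1.0, 0.8, n_t)
        x_c = rng.normal(0.0, 0.8, n_c)
        tau = -0.9
        df = pd.DataFrame({
            "biome": "dry",
            "property_id": np.r_[np.zeros(n_t), np.ones(n_c)],
            "x": np.r_[x_t, x_c],
        })
        df["y_loss"] = (0.8 * df["x"]
                        + tau * np.r_[np.ones(n_t), np.zeros(n_c)]
                        + rng.normal(0, 0.3, n_t + n_c))
        treated = np.r_[np.ones(n_t, bool), np.zeros(n_c, bool)]
        m = tm.match_nearest_neighbor(df, treated, ["x"])
        raw = tm.raw_att(m)
        adj, tt_adj = tm.bias_adjust(m, df, ["x"])
        assert adj < raw  # gap correction pushes the estimate down
        se_raw, cis_raw = tm.att_variance(m)
        se_adj, cis_adj = tm.att_variance(m, tt=tt_adj)
        assert cis_adj[90][1] < 0  # adjusted effect significant
        assert abs(adj - tau) < abs(raw - tau)


class TestVariance:
    def _pairs(self, tt, controls=None):
        n = len(tt)
        c = np.arange(n) + 100 if controls is None else np.asarray(controls)
        return tm.MatchedSample(np.arange(n), c, np.zeros(n),
                                np.asarray(tt, float),
                                "mahalanobis_trimmed", "dry")

    def test_degenerate_pairs_zero_se(self):
        m = self._pairs([0.5, 0.5, 0.5])
        se, cis = tm.att_variance(m)
        assert se == 0.0
        lo, hi = cis[95]
        assert lo == hi == pytest.approx(0.5)

    def test_plain_mode_classical_form_without_reuse(self):
        tt = [1.0, 0.0, -1.0, 1.0, 0.0]
        m = self._pairs(tt)
        se, _ = tm.att_variance(m)
        assert se == pytest.approx(np.std(tt, ddof=1) / np.sqrt(5))

    def test_reuse_inflates_plain_se(self):
        tt = [1.0, 0.0, -1.0, 1.0]
        no_reuse = self._pairs(tt)
        reuse = self._pairs(tt, controls=[100, 100, 100, 101])
        assert tm.att_variance(reuse)[0] > tm.att_variance(no_reuse)[0]

    def test_single_pair_raises(self):
        with pytest.raises(ValueError):
            tm.att_variance(self._pairs([1.0]))

    def test_cis_nested(self):
        m = self._pairs([1.0, 0.0, -1.0, 0.5])
        _, cis = tm.att_variance(m)
        assert cis[99][0] <= cis[95][0] <= cis[90][0]
        assert cis[90][1] <= cis[95][1] <= cis[99][1]

    def test_null_ci_coverage(self):
        # no treatment effect: the 95% interval should cover zero at
        # roughly its nominal rate across replicate draws
        cover = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            n_t, n_c = 120, 400
            df = pd.DataFrame({
                "biome": "dry",
                "property_id": rng.integers(0, 20, n_t + n_c),
                "x": rng.normal(0, 1, n_t + n_c),
            })
            p = 1 / (1 + np.exp(-(-2.0 + 0.4 * df["x"])))
            df["y_loss"] = (rng.random(n_t + n_c) < p).astype(float)
            treated = np.r_[np.ones(n_t, bool), np.zeros(n_c, bool)]
            m = tm.match_nearest_neighbor(df, treated, ["x"])
            _, cis = tm.att_variance(m)
            lo, hi = cis[95]
            cover += lo <= 0 <= hi
        assert abs(cover / reps - 0.95) < 0.03 + 2 * np.sqrt(
            0.95 * 0.05 / reps)

    def test_heteroscedastic_mode_runs(self):
        df, treated, lps = random_instance(17)
        m = tm.match_nearest_neighbor(df, treated, ["a", "b", "c"])
        se, cis = tm.att_variance(m, mode="heteroscedastic", sample=df,
                                  covariates=["a", "b", "c"])
        assert se >= 0 and np.isfinite(se)


class TestSelectEstimator:
    def test_identical_candidates_first_wins(self):
        df, treated, lps = random_instance(21)
        metric, m, rows = tm.select_estimator(
            df, treated, ["a", "b", "c"], lps=lps,
            candidates=("mahalanobis_trimmed", "mahalanobis_trimmed"))
        assert metric == "mahalanobis_trimmed"

    def test_selects_better_balanced_metric(self):
        # the score carries a confounder ("a") that the plain distance
        # covariates miss entirely; the augmented metric matches on it and
        # must be preferred once balance is judged over all three
        from tenurematch.balance import max_abs_nd
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 250
            df = pd.DataFrame({
                "biome": "dry",
                "property_id": rng.integers(0, 12, n),
                "a": rng.normal(0, 1, n),
                "b": rng.normal(0, 1, n),
                "c": rng.normal(0, 1, n),
                "y_loss": rng.integers(0, 2, n),
            })
            eta = 2.0 * df["a"] - 0.8
            treated = (rng.random(n) < 1 / (1 + np.exp(-eta))).to_numpy()
            lps = pd.Series(eta, index=df.index)
            summaries = {}
            for metric in ("mahalanobis_trimmed", "ps_augmented"):
                m = tm.match_nearest_neighbor(df, treated, ["b", "c"],
                                              metric=metric, lps=lps)
                rows = tm.balance_table(df, treated, ["a", "b", "c"],
                                        matched=m)
                summaries[metric] = max_abs_nd(rows)
            sel, _, _ = tm.select_estimator(
                df, treated, ["b", "c"], lps=lps,
                balance_covariates=["a", "b", "c"])
            assert sel == min(summaries, key=summaries.get)
            assert sel == "ps_augmented"

    def test_all_infeasible_raises(self):
        df, treated, lps = random_instance(5)
        empty = np.zeros(len(df), bool)  # no treated anywhere
        with pytest.raises(MatchingInfeasibleError):
            tm.select_estimator(df, empty, ["a", "b", "c"], lps=lps)


class TestRunComparison:
    def test_tiny_treated_pool_is_na(self, study_frame):
        est = tm.run_comparison(
            study_frame.sample.iloc[:200],
            tm.ComparisonSpec(question="A", biome="dry"), min_treated=10**6)
        assert est.is_na
        assert "small treated pool" in est.na_reason

    def test_sign_convention_negative_under_protection(self):
        # generator suppresses clearing under protection; with a strong
        # effect the estimated ATT must come out negative
        cfg = tm.LandscapeConfig(
            grid_width=200, grid_height=200, n_properties=280, seed=31,
            effect_curve_params={"kind": "constant", "value": -0.15})
        L = tm.generate_landscape(cfg)
        frame = tm.build_frame(L.to_pixel_table(), fraction=0.3, seed=31)
        for biome in ("dry", "moist"):
            est = tm.run_comparison(
                frame.sample, tm.ComparisonSpec(question="A", biome=biome),
                spillover_pool=frame.spillover_pool)
            assert not est.is_na
            assert est.raw_att < 0
            assert est.bias_adjusted_att < 0

    def test_bookkeeping(self, question_a_estimate):
        est = question_a_estimate
        assert est.n_mc <= est.n_cp
        assert est.n_t == len(np.unique(est.matched.treated_ids))
        assert est.n_mc == len(np.unique(est.matched.control_ids))
        assert -1 <= est.raw_att <= 1

    def test_null_tenure_contrast(self, study_frame):
        # tenure plays no causal role in the generator: comparing
        # unprotected ejido to unprotected private pixels is a null test
        est = tm.run_comparison(
            study_frame.sample,
            tm.ComparisonSpec(question="C", biome="moist",
                              treated_tenure="ejido",
                              control_tenure="private",
                              protection_stratum="unprotected"),
            spillover_pool=study_frame.spillover_pool)
        assert not est.is_na
        assert abs(est.bias_adjusted_att) < 2 * est.se
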