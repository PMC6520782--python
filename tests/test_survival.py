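import numpy as np
import pandas as pd
import pytest

from dasurv.da import FeatureSet
from dasurv.survival import (
    binarize_risk,
    build_risk_profile,
    cox_univariate,
    evaluate_risk_groups,
    fit_feature_cox,
    km_estimate,
    risk_score,
)
from dasurv.synthetic import SimConfig, simulate_bundle

from .oracles import cox_by_grid


class TestKaplanMeier:
    def test_product_limit_by_hand(self):
        # 4 patients, deaths at t=1 and t=2, no censoring
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 1, 1])
        groups = np.array(["a", "a", "a", "a"] )
        curves, _, _ = km_estimate(
            np.concatenate([times, [9.0]]),
            np.concatenate([events, [1]]),
            np.concatenate([groups, ["b"]]),
        )
        s = curves["a"]
        assert s.loc[1.0] == pytest.approx(3 / 4)
        assert s.loc[2.0] == pytest.approx(1 / 2)

    def test_identical_groups_give_null_logrank(self):
        t = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        d = np.array([1, 0, 1, 1, 1, 0, 1, 1])
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        _, stat, p = km_estimate(t, d, g)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_no_events_reports_p_one(self):
        t = np.array([1.0, 2, 3, 4])
        d = np.zeros(4, dtype=int)
        g = np.array([0, 0, 1, 1])
        curves, stat, p = km_estimate(t, d, g)
        assert p == 1.0
        assert (curves[0] == 1.0).all()

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([1.0, 2.0], [1, 1], ["a", "a"])


class TestCoxUnivariate:
    def test_constant_covariate_is_uninformative(self):
        res = cox_univariate(np.ones(10), np.arange(1, 11.0), np.ones(10, dtype=int))
        assert res.b == 0.0 and res.hr == 1.0
        assert res.p_value == 1.0
        assert res.ci_low <= res.hr <= res.ci_high

    def test_matches_grid_search_oracle(self, survival_fixture):
        t, d, x = survival_fixture
        res = cox_univariate(x, t, d)
        b_grid = cox_by_grid(x - x.mean(), t, d)
        assert abs(res.b - b_grid) < 1e-4

    def test_matches_lifelines_on_tie_free_data(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(10)
        n = 60
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * x))
        d = (rng.random(n) > 0.25).astype(int)
        res = cox_univariate(x, t, d)
        df = pd.DataFrame({"x": x, "t": t, "e": d})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert res.b == pytest.approx(float(cph.params_["x"]), abs=1e-5)
        assert res.se == pytest.approx(float(cph.standard_errors_["x"]), abs=1e-4)

    def test_hr_and_ci_consistent(self, survival_fixture):
        t, d, x = survival_fixture
        res = cox_univariate(x, t, d)
        assert res.hr == pytest.approx(np.exp(res.b))
        assert res.ci_low <= res.hr <= res.ci_high

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            cox_univariate(np.arange(5.0), np.arange(1, 6.0), np.zeros(5, dtype=int))

    def test_perfect_separation_flagged(self):
        # the covariate orders survival perfectly and diverges
        t = np.array([1.0, 2, 3, 10, 11, 12])
        d = np.ones(6, dtype=int)
        x = np.array([1.0, 1, 1, 0, 0, 0])
        res = cox_univariate(x, t, d)
        assert res.flagged


class TestRiskScore:
    def test_direct_substitution(self):
        feats = pd.DataFrame([[0.5, 0.5]], index=["p0"], columns=["F1", "F2"])
        s = risk_score(feats, np.array([1.0, 2.0]))
        assert s.loc["p0"] == pytest.approx(1.5)

    def test_zero_coefficients_zero_scores(self):
        rng = np.random.default_rng(0)
        feats = pd.DataFrame(rng.random((4, 3)), columns=list("abc"))
        assert (risk_score(feats, np.zeros(3)) == 0).all()

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(1)
        feats = pd.DataFrame(rng.random((5, 3)), columns=list("abc"))
        b = rng.normal(size=3)
        s = risk_score(feats, b)
        for i in range(5):
            expected = sum(feats.iloc[i, j] * b[j] for j in range(3))
            assert s.iloc[i] == pytest.approx(expected)

    def test_linear_in_activities(self):
        rng = np.random.default_rng(2)
        feats = pd.DataFrame(rng.random((6, 4)))
        b = rng.normal(size=4)
        np.testing.assert_allclose(
            risk_score(feats * 3.0, b).to_numpy(),
            3.0 * risk_score(feats, b).to_numpy(),
        )

    def test_dimension_mismatch_rejected(self):
        feats = pd.DataFrame(np.ones((2, 3)))
        with pytest.raises(ValueError):
            risk_score(feats, np.ones(2))


class TestBinarizeRisk:
    def test_default_quantile_split_counts(self):
        scores = pd.Series(np.arange(1.0, 101.0))
        cutoff, group = binarize_risk(scores, prob=0.55)
        assert (group == "low").sum() == 55
        assert (group == "high").sum() == 45

    def test_median_split(self):
        scores = pd.Series([-2.0, -1.0, 1.0, 2.0])
        _, group = binarize_risk(scores, prob=0.5)
        assert list(group) == ["low", "low", "high", "high"]

    def test_shift_invariant(self):
        rng = np.random.default_rng(3)
        scores = pd.Series(rng.normal(size=50))
        _, g1 = binarize_risk(scores)
        _, g2 = binarize_risk(scores + 1000.0)
        pd.testing.assert_series_equal(g1, g2)

    def test_identical_scores_rejected(self):
        with pytest.raises(ValueError):
            binarize_risk(pd.Series(np.ones(10)))

    def test_low_fraction_close_to_prob_for_distinct_scores(self):
        rng = np.random.default_rng(4)
        n = 321
        scores = pd.Series(rng.normal(size=n))
        _, group = binarize_risk(scores, prob=0.55)
        assert abs((group == "low").mean() - 0.55) <= 1.0 / n + 1e-12


class TestPipelinePieces:
    def test_cox_recovers_planted_hazard_in_simulation(self):
        """Mean estimate near the generative log-HR across replicates."""
        estimates = []
        for rep in range(20):
            cfg = SimConfig(n_patients=500, n_genes=10, n_latent=2,
                            hazard_coef=0.8, seed=100 + rep)
            bundle, truth = simulate_bundle(cfg)
            res = cox_univariate(
                truth.latent_factors[:, 0],
                bundle.clinical["os_time"].to_numpy(),
                bundle.clinical["os_event"].to_numpy(),
            )
            estimates.append(res.b)
        assert abs(np.mean(estimates) - 0.8) < 0.15

    def test_evaluate_risk_groups_deterministic(self, trained_two, scaled_pair):
        _, _, feats = trained_two
        _, _, clin = scaled_pair
        p1 = build_risk_profile(feats, clin)
        p2 = build_risk_profile(feats, clin)
        pd.testing.assert_series_equal(p1.scores, p2.scores)
        e1 = evaluate_risk_groups(p1, clin)
        e2 = evaluate_risk_groups(p2, clin)
        pd.testing.assert_frame_equal(e1["summary"], e2["summary"])

    def test_joint_ridge_fit_available(self, trained_two, scaled_pair):
        _, _, feats = trained_two
        _, _, clin = scaled_pair
        results = fit_feature_cox(feats, clin, joint=True, ridge=0.5)
        assert len(results) == feats.activity.shape[1]
        assert all(np.isfinite(r.b) for r in results)

    def test_risk_profile_group_rule(self, trained_two, scaled_pair):
        _, _, feats = trained_two
        _, _, clin = scaled_pair
        prof = build_risk_profile(feats, clin)
        high = prof.scores > prof.cutoff
        assert ((prof.group == "high") == high).all()
        # scores reproducible from coefficients and activities
        np.testing.assert_allclose(
            prof.scores.to_numpy(),
            feats.activity.to_numpy() @ prof.coefficients.reindex(feats.feature_ids).to_numpy(),
        )
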