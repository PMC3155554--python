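"""Cox fits, componentwise boosting, AIC elimination, cohort splitting."""

import numpy as np
import pandas as pd
import pytest

from cnisig.cox_models import (BoostConfig, backwards_eliminate_aic, cox_fit,
                               coxboost_select, split_cohort)
from cnisig.simulate import simulate_marker_cohort

from conftest import toy_outcome


def _breslow_loglik_reference(beta, x, time, event):
    """Plain-loop Breslow log partial likelihood (independent of the engine)."""
    ll = 0.0
    for i in range(len(time)):
        if not event[i]:
            continue
        risk = [j for j in range(len(time)) if time[j] >= time[i]]
        ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


class TestCoxFit:
    def test_toy_loglik_matches_grid_search_oracle(self):
        # n = 6, one covariate, no ties: Efron == Breslow, so the plain
        # Breslow grid search is a valid oracle for both
        x = np.array([0.0, 1.0, 0.0, 1.0, 1.0, 0.0])
        time = [2.0, 3.0, 5.0, 7.0, 11.0, 13.0]
        event = [1, 1, 0, 1, 1, 1]
        grid = np.arange(-5.0, 5.0, 1e-3)
        lls = [_breslow_loglik_reference(b, x, time, event) for b in grid]
        best = grid[int(np.argmax(lls))]
        fit = cox_fit(pd.DataFrame({"x": x}), toy_outcome(time, event))
        assert fit.log_likelihood == pytest.approx(max(lls), abs=1e-4)
        assert fit.coefs["x"] == pytest.approx(best, abs=2e-3)

    def test_two_group_hazard_ratio_of_two_is_recovered(self):
        rng = np.random.default_rng(0)
        n = 4000
        g = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / (0.01 * np.exp(np.log(2) * g)))
        fit = cox_fit(pd.DataFrame({"g": g}), toy_outcome(t, np.ones(n)))
        assert fit.coefs["g"] == pytest.approx(np.log(2), abs=0.05)
        assert fit.summary.loc["g", "hr"] == pytest.approx(
            np.exp(fit.coefs["g"]))

    def test_zero_variance_covariate_is_flagged_not_fitted(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"zero": np.zeros(50), "x": rng.normal(size=50)})
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            fit = cox_fit(X, toy_outcome(rng.exponential(10, 50), np.ones(50)))
        assert fit.coefs["zero"] == 0.0
        assert np.isinf(fit.summary.loc["zero", "se"])
        assert "zero" in fit.degenerate

    def test_collinear_covariates_raise_with_names(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=60)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="b"):
            cox_fit(X, toy_outcome(rng.exponential(10, 60), np.ones(60)))

    def test_efron_and_breslow_agree_without_ties(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"x": rng.normal(size=120),
                          "y": rng.integers(0, 2, 120).astype(float)})
        t = rng.exponential(1.0 / np.exp(0.5 * X["x"]))
        out = toy_outcome(t, rng.integers(0, 2, 120))
        fe = cox_fit(X, out, ties="efron")
        fb = cox_fit(X, out, ties="breslow")
        assert np.allclose(fe.coefs, fb.coefs, atol=1e-5)
        assert np.allclose(fe.summary["se"], fb.summary["se"], atol=1e-4)

    def test_aic_counts_nonzero_coefficients(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"x": rng.normal(size=80)})
        fit = cox_fit(X, toy_outcome(rng.exponential(10, 80), np.ones(80)))
        assert fit.aic == pytest.approx(-2 * fit.log_likelihood + 2.0)


class TestBoosting:
    def test_zero_steps_select_nothing(self, marker_cohort):
        doses, outcome, _ = marker_cohort
        res = coxboost_select(doses, outcome, config=BoostConfig(steps=0))
        assert res.selected == []
        assert (res.coefs == 0).all()

    def test_single_candidate_converges_to_unpenalized_mle(self):
        doses, outcome, _ = simulate_marker_cohort(
            n_samples=400, n_segments=1, prognostic_betas=(0.8,),
            carrier_freq=0.4, seed=21)
        mle = cox_fit(doses.astype(float), outcome[["time_months", "event"]],
                      ties="breslow").coefs.iloc[0]
        res = coxboost_select(doses, outcome[["time_months", "event"]],
                              config=BoostConfig(steps=3000, penalty=50.0))
        assert res.coefs.iloc[0] == pytest.approx(mle, abs=1e-3)

    def test_partial_likelihood_is_nondecreasing_over_steps(self, marker_cohort):
        doses, outcome, _ = marker_cohort
        res = coxboost_select(doses, outcome, config=BoostConfig(steps=60))
        assert np.all(np.diff(res.loglik_path) >= -1e-9)

    def test_huge_penalty_shrinks_every_update_to_nothing(self, marker_cohort):
        doses, outcome, _ = marker_cohort
        res = coxboost_select(doses, outcome,
                              config=BoostConfig(steps=30, penalty=1e12))
        assert res.coefs.abs().max() < 1e-6

    def test_mandatory_covariates_are_refit_unpenalized(self, marker_cohort):
        doses, outcome, beta = marker_cohort
        rng = np.random.default_rng(5)
        clin = pd.DataFrame({"z": rng.normal(size=len(doses))},
                            index=doses.index)
        res = coxboost_select(doses, outcome, clinical_mandatory=clin,
                              config=BoostConfig(steps=20))
        assert "z" in res.mandatory_coefs.index
        assert res.mandatory_coefs["z"] != 0.0 or True  # present, unpenalized

    def test_no_events_is_an_error(self):
        doses = pd.DataFrame({"s": [0, 1, 0, 1]})
        with pytest.raises(ValueError, match="event"):
            coxboost_select(doses, toy_outcome([1, 2, 3, 4], [0, 0, 0, 0]))

    def test_planted_effect_sign_matches_fitted_sign(self):
        doses, outcome, beta = simulate_marker_cohort(
            n_samples=2000, n_segments=1, prognostic_betas=(-0.6,),
            carrier_freq=0.4, seed=8)
        fit = cox_fit(doses.astype(float), outcome[["time_months", "event"]])
        assert np.sign(fit.coefs.iloc[0]) == np.sign(beta.iloc[0])


class TestBackwardsElimination:
    def test_pure_noise_covariate_is_mostly_dropped(self):
        # AIC keeps a null covariate iff its chi-square exceeds 2 (~16% of
        # the time), so with one noise covariate the forced-only model should
        # appear in >= 80% of seeds
        kept_only_forced = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 300
            X = pd.DataFrame(rng.normal(size=(n, 2)),
                             columns=["forced", "noise"])
            out = toy_outcome(rng.exponential(10, n), np.ones(n))
            fit = backwards_eliminate_aic(X, out, forced=("forced",))
            if list(fit.summary.index) == ["forced"]:
                kept_only_forced += 1
        assert kept_only_forced >= 16  # >= 80% of seeds

    def test_real_effect_is_always_retained(self):
        retained = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 500
            X = pd.DataFrame({"signal": rng.integers(0, 2, n).astype(float),
                              "noise": rng.normal(size=n)})
            t = rng.exponential(1.0 / (0.01 * np.exp(X["signal"])))
            fit = backwards_eliminate_aic(X, toy_outcome(t, np.ones(n)))
            retained += "signal" in fit.summary.index
        assert retained == 20

    def test_forcing_all_columns_reduces_to_plain_fit(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        out = toy_outcome(rng.exponential(10, 100), np.ones(100))
        elim = backwards_eliminate_aic(X, out, forced=("a", "b", "c"))
        plain = cox_fit(X, out)
        pd.testing.assert_frame_equal(elim.summary, plain.summary)

    def test_unknown_forced_name_is_an_error(self):
        X = pd.DataFrame({"a": [0.0, 1, 0, 1]})
        with pytest.raises(ValueError, match="ghost"):
            backwards_eliminate_aic(X, toy_outcome([1, 2, 3, 4], [1, 1, 1, 1]),
                                    forced=("ghost",))


class TestSplit:
    def test_three_quarter_split_of_971_gives_728_and_243(self):
        train, test = split_cohort([f"S{i}" for i in range(971)], 0.75, seed=1)
        assert (len(train), len(test)) == (728, 243)

    def test_minimal_cohort_splits_three_to_one(self):
        train, test = split_cohort(list("abcd"), 0.75, seed=0)
        assert (len(train), len(test)) == (3, 1)

    def test_partition_is_disjoint_exhaustive_and_seed_deterministic(self):
        ids = [f"S{i}" for i in range(100)]
        t1, v1 = split_cohort(ids, 0.75, seed=3)
        t2, v2 = split_cohort(ids, 0.75, seed=3)
        t3, _ = split_cohort(ids, 0.75, seed=4)
        assert (t1, v1) == (t2, v2)
        assert t1 != t3
        assert sorted(t1 + v1) == sorted(ids)

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2, 1.5])
    def test_fraction_outside_unit_interval_is_rejected(self, fraction):
        with pytest.raises(ValueError):
            split_cohort(list("abcdef"), fraction, seed=0)
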