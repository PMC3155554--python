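"""Concordance, C-index comparison, time-dependent ROC, KM and log-rank."""

import numpy as np
import pandas as pd
import pytest

from cnisig.discrimination import (compare_cindex, concordance_index,
                                   km_curve, log_rank, td_roc)
from cnisig.simulate import simulate_marker_cohort

from conftest import toy_outcome


def _brute_force_c(score, time, event):
    """Exhaustive usable-pair enumeration with the documented conventions."""
    conc = disc = tied = 0
    n = len(score)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            first = (time[i] < time[j] and event[i]) or \
                    (time[i] == time[j] and event[i] and not event[j])
            if not first:
                continue
            if score[i] > score[j]:
                conc += 1
            elif score[i] < score[j]:
                disc += 1
            else:
                tied += 1
    return (conc + 0.5 * tied) / (conc + disc + tied), conc, disc, tied


class TestConcordance:
    def test_mixed_censoring_fixture_matches_pair_enumeration_exactly(self):
        score = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.0])
        time = np.array([5.0, 8.0, 3.0, 9.0, 3.0, 1.0, 7.0, 2.0, 6.0, 4.0])
        event = np.array([1, 0, 1, 1, 0, 1, 0, 1, 1, 0])
        res = concordance_index(score, toy_outcome(time, event))
        c, conc, disc, tied = _brute_force_c(score, time, event.astype(bool))
        assert res.c == pytest.approx(c, abs=1e-12)
        assert (res.concordant, res.discordant, res.tied_risk) == (conc, disc, tied)

    def test_agrees_with_scikit_survival_reference(self):
        sksurv = pytest.importorskip("sksurv.metrics")
        rng = np.random.default_rng(0)
        n = 200
        score = rng.normal(size=n)
        time = rng.exponential(10, n)
        event = rng.integers(0, 2, n).astype(bool)
        res = concordance_index(score, toy_outcome(time, event.astype(int)))
        ref = sksurv.concordance_index_censored(event, time, score)
        assert res.c == pytest.approx(ref[0], abs=1e-12)

    def test_perfectly_ordered_scores_give_c_of_one(self):
        t = np.arange(1.0, 11.0)
        res = concordance_index(-t, toy_outcome(t, np.ones(10)))
        assert res.c == 1.0

    def test_constant_score_gives_half(self):
        t = np.arange(1.0, 11.0)
        assert concordance_index(np.zeros(10), toy_outcome(t, np.ones(10))).c == 0.5

    def test_invariant_under_strictly_monotone_transform(self):
        rng = np.random.default_rng(1)
        score = rng.normal(size=80)
        out = toy_outcome(rng.exponential(5, 80), rng.integers(0, 2, 80))
        c1 = concordance_index(score, out).c
        c2 = concordance_index(np.exp(3 * score) + 7, out).c
        assert c1 == c2

    def test_no_usable_pairs_is_an_error(self):
        with pytest.raises(ValueError, match="usable"):
            concordance_index([1.0, 2.0], toy_outcome([5.0, 6.0], [0, 0]))


class TestCompare:
    def test_model_against_itself_is_a_null_comparison(self):
        rng = np.random.default_rng(2)
        score = rng.normal(size=100)
        out = toy_outcome(rng.exponential(5, 100), np.ones(100))
        res = compare_cindex(score, score, out, b_boot=50, seed=0)
        assert res.p == pytest.approx(1.0)
        assert res.mean_diff == 0.0

    def test_signal_model_beats_noise_model(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            doses, outcome, beta = simulate_marker_cohort(
                n_samples=500, n_segments=6, seed=300 + seed)
            signal = doses.to_numpy() @ beta.to_numpy()
            noise = np.random.default_rng(seed).normal(size=len(doses))
            res = compare_cindex(signal, noise,
                                 outcome[["time_months", "event"]],
                                 b_boot=100, seed=seed)
            hits += (res.p < 0.01) and (res.mean_diff > 0)
        assert hits >= n_seeds - 1

    def test_doubling_bootstrap_keeps_difference_sign(self):
        rng = np.random.default_rng(3)
        doses, outcome, beta = simulate_marker_cohort(n_samples=300, seed=9)
        signal = doses.to_numpy() @ beta.to_numpy()
        noise = rng.normal(size=len(doses))
        r1 = compare_cindex(signal, noise, outcome[["time_months", "event"]],
                            b_boot=50, seed=1)
        r2 = compare_cindex(signal, noise, outcome[["time_months", "event"]],
                            b_boot=100, seed=1)
        assert np.sign(r1.mean_diff) == np.sign(r2.mean_diff)

    def test_too_few_bootstrap_replicates_is_an_error(self):
        with pytest.raises(ValueError):
            compare_cindex([1.0, 2.0], [2.0, 1.0],
                           toy_outcome([1.0, 2.0], [1, 1]), b_boot=5)


def _empirical_roc(score, label):
    """Threshold-by-threshold empirical ROC of a binary label (loops)."""
    sens, spec = [], []
    for c in np.unique(score):
        hi = score > c
        sens.append((hi & (label == 1)).sum() / max((label == 1).sum(), 1))
        spec.append((~hi & (label == 0)).sum() / max((label == 0).sum(), 1))
    return np.array(sens), np.array(spec)


class TestTdRoc:
    def test_uncensored_case_reduces_to_empirical_roc_exactly(self):
        rng = np.random.default_rng(4)
        n = 150
        score = rng.normal(size=n)
        time = rng.exponential(60 * np.exp(-score), n).clip(0.01)
        out = toy_outcome(time, np.ones(n))
        horizon = 60.0
        curve = td_roc(score, out, horizon)
        label = (time <= horizon).astype(int)
        sens, spec = _empirical_roc(score, label)
        assert np.allclose(curve.sensitivity, sens, atol=1e-12)
        assert np.allclose(curve.specificity, spec, atol=1e-12)

    def test_strong_risk_score_has_high_auc(self):
        rng = np.random.default_rng(5)
        n = 400
        score = rng.normal(size=n)
        time = rng.exponential(40 * np.exp(-2.5 * score), n).clip(0.01)
        curve = td_roc(score, toy_outcome(time, np.ones(n)), 40.0)
        assert curve.auc > 0.9

    def test_independent_score_sits_at_chance(self):
        rng = np.random.default_rng(6)
        n = 1000
        score = rng.normal(size=n)
        time = rng.exponential(100, n)
        event = (time <= 240).astype(int)
        curve = td_roc(score, toy_outcome(np.minimum(time, 240), event), 120.0)
        assert curve.auc == pytest.approx(0.5, abs=0.05)

    def test_no_events_before_horizon_is_an_error(self):
        with pytest.raises(ValueError, match="events"):
            td_roc([1.0, 2.0, 3.0], toy_outcome([50.0, 60.0, 70.0], [0, 0, 1]),
                   20.0)

    def test_horizon_beyond_follow_up_is_an_error(self):
        with pytest.raises(ValueError, match="follow-up"):
            td_roc([1.0, 2.0], toy_outcome([10.0, 20.0], [1, 1]), 100.0)

    def test_curves_are_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        n = 300
        score = rng.normal(size=n)
        time = rng.exponential(80 * np.exp(-score), n).clip(0.01)
        event = rng.integers(0, 2, n)
        curve = td_roc(score, toy_outcome(time, np.maximum(event, time < 5)),
                       60.0)
        assert np.all(np.diff(curve.sensitivity) <= 1e-12)
        assert np.all(np.diff(curve.specificity) >= -1e-12)


class TestKmLogRank:
    def test_km_without_censoring_is_one_minus_empirical_cdf(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        curves = km_curve(toy_outcome(t, np.ones(5)))
        km = curves["all"]
        for tt, s in zip(km["time"], km["survival"]):
            assert s == pytest.approx((t > tt).mean())

    def test_proportional_hazards_groups_are_detected(self):
        detected = 0
        for seed in range(5):
            rng = np.random.default_rng(50 + seed)
            n = 500
            g = rng.integers(0, 2, n)
            t = rng.exponential(1.0 / (0.01 * 2.0 ** g))
            res = log_rank(toy_outcome(t, np.ones(n)),
                           np.where(g == 1, "B", "A"))
            detected += res.p < 0.001
        assert detected == 5

    def test_group_without_events_is_an_error(self):
        out = toy_outcome([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 0])
        with pytest.raises(ValueError, match="no events"):
            km_curve(out, np.array(["a", "a", "b", "b"]))

    def test_missing_group_label_is_an_error(self):
        out = toy_outcome([1.0, 2.0, 3.0], [1, 1, 1])
        with pytest.raises(ValueError):
            log_rank(out, np.array(["a", None, "b"], dtype=object))
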