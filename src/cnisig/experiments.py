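"""Desk-scale recovery, ordering and calibration experiments.

Self-contained experiments that exercise the whole pipeline against planted
ground truth: worked-example arithmetic on the reference cohort's published
descriptive counts, segmentation and marker-selection recovery, the
discrimination ordering of the four model families, brute-force oracle
equivalences for the core statistics, and calibration of the permutation FDR
and the log-rank test.  Each function takes a seed and returns a flat dict of
numbers; they back both the acceptance checks in the test suite and the
reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bma import BmaConfig, bma_posterior_effects
from .cox_models import BoostConfig, cox_fit, coxboost_select, split_cohort
from .discrimination import concordance_index, log_rank, td_roc
from .pipeline import PipelineConfig, run_full_analysis
from .segmentation import SegmentationParams, build_common_grid, \
    reduce_running_median, segment_profiles
from .simulate import default_config, default_layout, null_config, \
    simulate_marker_cohort, simulate_probe_matrix
from .subtypes import subtype_frequency_test

__all__ = [
    "worked_examples", "segmentation_recovery", "selection_recovery",
    "discrimination_ordering", "oracle_gaps", "calibration",
]

# descriptive counts of the reference cohort (inputs for the worked examples)
COHORT_N = 971
SUBTYPE_COUNTS = {"LUM A": 389, "LUM B": 156, "HER2": 158, "TNBC": 184,
                  "missing": 84}
RISK_GROUP_COUNTS = {"low": 153, "no-CNI": 449, "high": 369}


def worked_examples(seed: int = 0) -> dict:
    """Split sizes and descriptive percentages from the published counts."""
    train, test = split_cohort([f"P{i:04d}" for i in range(COHORT_N)],
                               train_fraction=0.75, seed=seed)
    out = {"train_n": len(train), "test_n": len(test)}
    for name, cnt in SUBTYPE_COUNTS.items():
        out[f"subtype_pct_{name}"] = round(100.0 * cnt / COHORT_N, 1)
    total = sum(RISK_GROUP_COUNTS.values())
    for name, cnt in RISK_GROUP_COUNTS.items():
        out[f"risk_group_pct_{name}"] = round(100.0 * cnt / total, 1)
    return out


def _planted_bin_spans(config, layout, group_size=25):
    """Chromosome-local (start_bin, stop_bin) per planted event."""
    spans = {}
    for ev in config.events:
        spans[ev.name] = (ev.chrom, ev.start_probe // group_size,
                          ev.stop_probe // group_size)
    return spans


def segmentation_recovery(seed: int = 0, n_samples: int = 60) -> dict:
    """Breakpoint and dose recovery on the default 4 × 2,500-probe genome.

    Twelve planted one-copy events under sd 0.15 probe noise; measures the
    fraction of planted breakpoints matched by a common-grid boundary within
    ±1 bin and the entry-wise agreement between the dose matrix and the
    planted truth expanded to bins.
    """
    cfg = default_config(n_samples=n_samples, seed=seed)
    layout = default_layout()
    params = SegmentationParams()
    pm, truth = simulate_probe_matrix(cfg, layout)
    red = reduce_running_median(pm, params.group_size)
    prof = segment_profiles(red, params, seed=seed)
    grid, doses = build_common_grid(prof, red, params)

    spans = _planted_bin_spans(cfg, layout, params.group_size)
    boundaries = {c: set() for c in red.chromosomes}
    for chrom, grp in grid.groupby("chrom"):
        for b in grp["start_bin"]:
            if b > 0:
                boundaries[chrom].add(int(b))
    hits = total = 0
    for chrom, b0, b1 in spans.values():
        for target in (b0, b1 + 1):
            total += 1
            hits += any(abs(target - b) <= 1 for b in boundaries[chrom])

    # expand both truth and grid doses to per-bin matrices and compare
    n_bins = len(red.bins)
    chrom_offset = {}
    off = 0
    for c in red.chromosomes:
        chrom_offset[c] = off
        off += len(red.chrom_bin_index(c))
    truth_bins = np.zeros((n_samples, n_bins), dtype=int)
    for ev in cfg.events:
        b0, b1 = spans[ev.name][1], spans[ev.name][2]
        o = chrom_offset[ev.chrom]
        truth_bins[:, o + b0:o + b1 + 1] = \
            truth.doses[ev.name].to_numpy()[:, None]
    grid_bins = np.zeros((n_samples, n_bins), dtype=int)
    for k, row in grid.iterrows():
        o = chrom_offset[row["chrom"]]
        sl = slice(o + row["start_bin"], o + row["stop_bin"] + 1)
        grid_bins[:, sl] = doses[row["segment_id"]].to_numpy()[:, None]

    return {
        "breakpoint_recovery_pct": round(100.0 * hits / total, 1),
        "dose_accuracy_pct": round(100.0 * (truth_bins == grid_bins).mean(), 2),
        "n_common_segments": int(len(grid)),
    }


def selection_recovery(seed: int = 0, n_seeds: int = 10) -> dict:
    """Boosted-selection recovery of 6 planted markers among 150 candidates."""
    tp, fp = [], []
    base = np.random.SeedSequence(seed).generate_state(n_seeds) % (2 ** 31)
    for s in base:
        doses, outcome, beta = simulate_marker_cohort(n_samples=728,
                                                      seed=int(s))
        res = coxboost_select(doses, outcome[["time_months", "event"]],
                              config=BoostConfig(steps=100))
        true = set(beta.index[beta != 0])
        sel = set(res.selected)
        tp.append(len(sel & true))
        fp.append(len(sel - true))
    return {"true_markers_selected_median": float(np.median(tp)),
            "false_positives_median": float(np.median(fp)),
            "n_true_markers": 6}


def discrimination_ordering(seed: int = 0, n_signal: int = 800,
                            n_null: int = 600, n_null_seeds: int = 3) -> dict:
    """Test-set C-indices of the model families on signal and null cohorts.

    The null level is the mean over ``n_null_seeds`` independent signal-free
    cohorts, each scored on a 50/50 split: a single 25% test split estimates
    C with an SD near 0.05, too coarse to locate the chance level on its own;
    halving the split and averaging seeds brings the SE below 0.02 without
    changing the quantity being estimated.
    """
    import tempfile
    with tempfile.TemporaryDirectory() as tmp:
        sig = run_full_analysis(PipelineConfig(
            out_dir=f"{tmp}/signal",
            simulation=default_config(n_samples=n_signal, seed=seed),
            split_seed=seed))
        null_full, null_clin = [], []
        for k in range(1, n_null_seeds + 1):
            nul = run_full_analysis(PipelineConfig(
                out_dir=f"{tmp}/null{k}",
                simulation=null_config(n_samples=n_null, seed=seed + k),
                split_seed=seed + k, train_fraction=0.5))
            mn = nul["metrics"].set_index("model")
            null_full.append(float(mn.loc["full", "c_index_test"]))
            null_clin.append(float(mn.loc["clinical", "c_index_test"]))
    ms = sig["metrics"].set_index("model")
    return {
        "c_index_full_test": round(float(ms.loc["full", "c_index_test"]), 3),
        "c_index_clinical_test": round(
            float(ms.loc["clinical", "c_index_test"]), 3),
        "c_index_full_minus_clinical_test": round(
            float(ms.loc["full", "c_index_test"]
                  - ms.loc["clinical", "c_index_test"]), 3),
        "null_c_index_full_test": round(float(np.mean(null_full)), 3),
        "null_c_index_clinical_test": round(float(np.mean(null_clin)), 3),
    }


def _cindex_enumeration_gap(seed: int) -> float:
    rng = np.random.default_rng(seed)
    score = rng.normal(size=10)
    time = rng.exponential(10, 10).round(0).clip(1)
    event = rng.integers(0, 2, 10)
    event[0] = 1
    conc = disc = tied = 0
    for i in range(10):
        for j in range(10):
            if i == j:
                continue
            first = (time[i] < time[j] and event[i]) or \
                    (time[i] == time[j] and event[i] and not event[j])
            if first:
                conc += score[i] > score[j]
                disc += score[i] < score[j]
                tied += score[i] == score[j]
    expected = (conc + 0.5 * tied) / (conc + disc + tied)
    got = concordance_index(score, pd.DataFrame(
        {"time_months": time.astype(float), "event": event})).c
    return abs(got - expected)


def _cox_gridsearch_gap(seed: int) -> float:
    # fixed balanced design (keeps the likelihood bounded, no separation);
    # the seed jitters the gaps between event times without reordering them
    rng = np.random.default_rng(seed)
    x = np.array([0.0, 1.0, 0.0, 1.0, 1.0, 0.0])
    time = np.array([2.0, 3.0, 5.0, 7.0, 11.0, 13.0]) + rng.uniform(0, 0.5, 6)
    event = np.array([1, 1, 0, 1, 1, 1])
    grid = np.arange(-5.0, 5.0, 1e-3)

    def pl(beta):  # Breslow reference, plain loops (no ties by construction)
        ll = 0.0
        for i in range(6):
            if not event[i]:
                continue
            risk = np.exp(beta * x[time >= time[i]])
            ll += beta * x[i] - np.log(risk.sum())
        return ll

    best = max(pl(b) for b in grid)
    fit = cox_fit(pd.DataFrame({"x": x}),
                  pd.DataFrame({"time_months": time, "event": event}))
    return abs(fit.log_likelihood - best)


def _bma_reference_gap(seed: int) -> float:
    """Stepwise window vs an independent exhaustive 2^8 enumeration (lifelines)."""
    from lifelines import CoxPHFitter
    doses, outcome, _ = simulate_marker_cohort(
        n_samples=300, n_segments=8, prognostic_betas=(1.0, -0.8),
        carrier_freq=0.4, seed=seed)
    X = doses.astype(float).reset_index(drop=True)
    out = outcome[["time_months", "event"]].reset_index(drop=True)
    n_events = int(out["event"].sum())
    names = list(X.columns)
    bics, members = [], []
    for mask in range(2 ** 8):
        cols = [names[j] for j in range(8) if mask >> j & 1]
        if cols:
            df = X[cols].copy()
            df["T"], df["E"] = out["time_months"], out["event"]
            cph = CoxPHFitter()
            cph.fit(df, "T", "E")
            ll = float(cph.log_likelihood_)
        else:
            # null partial likelihood via a zero-variance-free trick: lifelines
            # needs >=1 covariate, so compute directly
            from cnisig._coxph import SurvivalData, breslow_loglik
            sd = SurvivalData(out["time_months"], out["event"])
            ll = breslow_loglik(sd, np.zeros(len(out)))
        bics.append(-2 * ll + len(cols) * np.log(n_events))
        members.append(frozenset(cols))
    bics = np.array(bics)
    window = 2.0 * np.log(20.0)
    keep = bics <= bics.min() + window
    post = np.exp(-(bics[keep] - bics.min()) / 2)
    post /= post.sum()
    ref = pd.Series(0.0, index=names)
    for m, pr in zip([m for m, k in zip(members, keep) if k], post):
        for name in m:
            ref[name] += pr
    got = bma_posterior_effects(X, out, BmaConfig(max_exhaustive=4))
    return float((got.effect_probability - ref).abs().max())


def _fisher_gap(seed: int) -> float:
    from scipy import stats
    doses = pd.DataFrame({"seg": [1, 1, 1, 0, 0, 0, 0, 0, 1, 0, 0, 0]})
    labels = np.array(["A"] * 6 + ["B"] * 6)
    res = subtype_frequency_test(doses, labels, b_perm=100, seed=seed)
    a, b, c, d = 3, 1, 3, 5  # dose x group table of the fixture
    rv = stats.hypergeom(a + b + c + d, a + b, a + c)
    p_obs = rv.pmf(a)
    p_ref = sum(rv.pmf(k) for k in range(0, min(a + b, a + c) + 1)
                if rv.pmf(k) <= p_obs * (1 + 1e-9))
    return abs(float(res["p"].iloc[0]) - p_ref)


def _tdroc_gap(seed: int) -> float:
    rng = np.random.default_rng(seed)
    n = 120
    score = rng.normal(size=n)
    time = rng.exponential(60 * np.exp(-score), n).clip(0.01)
    out = pd.DataFrame({"time_months": time, "event": np.ones(n, dtype=int)})
    curve = td_roc(score, out, 60.0)
    label = (time <= 60.0).astype(int)
    gaps = []
    for k, c in enumerate(curve.thresholds):
        hi = score > c
        sens = (hi & (label == 1)).sum() / (label == 1).sum()
        spec = (~hi & (label == 0)).sum() / (label == 0).sum()
        gaps.append(abs(curve.sensitivity[k] - sens))
        gaps.append(abs(curve.specificity[k] - spec))
    return float(max(gaps))


def oracle_gaps(seed: int = 0) -> dict:
    """Max deviations of each statistic from its brute-force reference."""
    return {
        "cindex_enumeration_gap": round(_cindex_enumeration_gap(seed), 12),
        "cox_loglik_gridsearch_gap": round(_cox_gridsearch_gap(seed), 6),
        "bma_exhaustive_gap": round(_bma_reference_gap(seed), 6),
        "fisher_hypergeometric_gap": round(_fisher_gap(seed), 12),
        "tdroc_empirical_gap": round(_tdroc_gap(seed), 12),
    }


def calibration(seed: int = 0, n_logrank: int = 1000) -> dict:
    """Null calibration of the permutation FDR and the log-rank test."""
    flagged = []
    base = np.random.SeedSequence((seed, 1)).generate_state(3) % (2 ** 31)
    for s in base:
        rng = np.random.default_rng(int(s))
        n = 600
        labels = rng.choice(["LUM A", "LUM B", "HER2", "TNBC"], n)
        doses = pd.DataFrame(
            {f"s{j}": rng.choice([-1, 0, 1], n, p=[0.1, 0.75, 0.15])
             for j in range(50)})
        res = subtype_frequency_test(doses, labels, b_perm=200, seed=int(s))
        flagged.append((res["fdr"] < 0.01).mean())

    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    rejections = 0
    for _ in range(n_logrank):
        t = rng.exponential(100, 120)
        g = np.repeat(["A", "B"], 60)
        res = log_rank(pd.DataFrame({"time_months": t,
                                     "event": np.ones(120, dtype=int)}), g)
        rejections += res.p < 0.05
    return {
        "fdr_null_flagged_pct": round(100.0 * float(np.mean(flagged)), 2),
        "logrank_type1_rate": round(rejections / n_logrank, 3),
    }
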