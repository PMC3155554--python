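"""Model discrimination and survival comparison.

Harrell's concordance index with explicit pair counts, a bootstrap two-sample
t comparison of C-indices between models, time-dependent ROC curves at fixed
horizons using the Kaplan–Meier-weighted cumulative/dynamic estimator, and
Kaplan–Meier / log-rank wrappers (lifelines).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "ConcordanceResult",
    "CindexComparison",
    "TdRocCurve",
    "concordance_index",
    "compare_cindex",
    "td_roc",
    "km_curve",
    "log_rank",
]


@dataclass(frozen=True)
class ConcordanceResult:
    c: float
    se: float
    concordant: int
    discordant: int
    tied_risk: int

    @property
    def n_usable(self) -> int:
        return self.concordant + self.discordant + self.tied_risk


def concordance_index(risk_score, outcome: pd.DataFrame) -> ConcordanceResult:
    """Harrell's C over usable pairs; higher score = higher predicted hazard.

    A pair is usable when the ordering of event times is determinable under
    censoring: the earlier time carries an event (a time tie is usable only
    when exactly one member is an event; both-event ties are excluded).  Tied
    risk scores count ½.  The SE is the binomial counting estimator
    ``sqrt(c(1−c)/n_usable)``.
    """
    x = np.asarray(risk_score, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("risk scores must be finite")
    t = outcome["time_months"].to_numpy(dtype=float)
    e = outcome["event"].to_numpy(dtype=int).astype(bool)

    # pair (i, j) usable with i the determinable-first member
    first = (t[:, None] < t[None, :]) & e[:, None]
    first |= (t[:, None] == t[None, :]) & e[:, None] & ~e[None, :]
    conc = int(np.sum(first & (x[:, None] > x[None, :])))
    disc = int(np.sum(first & (x[:, None] < x[None, :])))
    tied = int(np.sum(first & (x[:, None] == x[None, :])))
    n_usable = conc + disc + tied
    if n_usable == 0:
        raise ValueError("no usable pairs for concordance")
    c = (conc + 0.5 * tied) / n_usable
    se = float(np.sqrt(max(c * (1 - c), 0.0) / n_usable))
    return ConcordanceResult(float(c), se, conc, disc, tied)


@dataclass(frozen=True)
class CindexComparison:
    t_stat: float
    df: float
    p: float
    mean_diff: float  # mean C(A) − mean C(B) over bootstrap replicates
    c_a: float
    c_b: float


def compare_cindex(risk_a, risk_b, outcome: pd.DataFrame,
                   b_boot: int = 200, seed: int = 0) -> CindexComparison:
    """Bootstrap two-sample t-test on replicate C-indices of two models.

    Both models must be scored on the same samples; each bootstrap resample
    re-evaluates both C-indices, and an unpaired two-sample t-test compares
    the two replicate sets.
    """
    if b_boot < 10:
        raise ValueError("b_boot must be at least 10")
    a = np.asarray(risk_a, dtype=float)
    b = np.asarray(risk_b, dtype=float)
    if a.shape != b.shape or len(a) != len(outcome):
        raise ValueError("models must be evaluated on the same samples")
    rng = np.random.default_rng(seed)
    n = len(a)
    cs_a, cs_b = [], []
    for _ in range(b_boot):
        idx = rng.integers(0, n, n)
        sub = outcome.iloc[idx]
        try:
            cs_a.append(concordance_index(a[idx], sub).c)
            cs_b.append(concordance_index(b[idx], sub).c)
        except ValueError:  # degenerate resample (no usable pairs)
            continue
    cs_a, cs_b = np.array(cs_a), np.array(cs_b)
    if np.allclose(cs_a, cs_b):
        return CindexComparison(0.0, float(2 * len(cs_a) - 2), 1.0,
                                float(cs_a.mean() - cs_b.mean()),
                                concordance_index(a, outcome).c,
                                concordance_index(b, outcome).c)
    res = stats.ttest_ind(cs_a, cs_b, equal_var=False)
    return CindexComparison(float(res.statistic), float(res.df),
                            float(res.pvalue), float(cs_a.mean() - cs_b.mean()),
                            concordance_index(a, outcome).c,
                            concordance_index(b, outcome).c)


def _km_survival_at(time: np.ndarray, event: np.ndarray, horizon: float) -> float:
    """Kaplan–Meier survival probability at ``horizon`` (numpy, no overhead)."""
    if time.size == 0:
        return 1.0
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    s = 1.0
    n_at_risk = t.size
    i = 0
    while i < t.size and t[i] <= horizon:
        j = i
        d = 0
        while j < t.size and t[j] == t[i]:
            d += e[j]
            j += 1
        if d:
            s *= 1.0 - d / n_at_risk
        n_at_risk -= j - i
        i = j
    return float(s)


@dataclass
class TdRocCurve:
    horizon: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def td_roc(risk_score, outcome: pd.DataFrame, horizon: float) -> TdRocCurve:
    """Cumulative/dynamic time-dependent ROC with Kaplan–Meier weighting.

    Case status at the horizon is D(t)=1 if the event occurred by ``t``;
    censoring before ``t`` is handled by conditioning on the risk-score
    stratum: sensitivity(c) = P(X>c | D(t)=1) and specificity(c) =
    P(X≤c | D(t)=0) are estimated from KM survival within {X>c} / {X≤c} via
    Bayes' rule.  The resulting curve is monotonized (cumulative maximum) and
    AUC computed by the trapezoid rule.  With no censoring before the horizon
    this reduces exactly to the empirical ROC of the binary event-by-t label.
    """
    x = np.asarray(risk_score, dtype=float)
    t = outcome["time_months"].to_numpy(dtype=float)
    e = outcome["event"].to_numpy(dtype=int)
    if horizon > t.max():
        raise ValueError("horizon exceeds observed follow-up")
    if not np.any((t <= horizon) & (e == 1)):
        raise ValueError("no events observed before the horizon")

    s_marg = _km_survival_at(t, e, horizon)
    cum_inc = 1.0 - s_marg
    thresholds = np.unique(x)
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for k, c in enumerate(thresholds):
        hi = x > c
        p_hi = hi.mean()
        s_hi = _km_survival_at(t[hi], e[hi], horizon) if hi.any() else 1.0
        s_lo = _km_survival_at(t[~hi], e[~hi], horizon) if (~hi).any() else 1.0
        sens[k] = (1.0 - s_hi) * p_hi / cum_inc if cum_inc > 0 else 0.0
        spec[k] = s_lo * (1.0 - p_hi) / s_marg if s_marg > 0 else 0.0
    sens = np.clip(sens, 0.0, 1.0)
    spec = np.clip(spec, 0.0, 1.0)

    # thresholds ascend → sensitivity should fall, specificity rise; the naive
    # KM plug-in can jitter under censoring, so enforce monotone shape
    sens = np.maximum.accumulate(sens[::-1])[::-1]
    spec = np.maximum.accumulate(spec)

    fpr = np.concatenate([[1.0], 1.0 - spec, [0.0]])
    tpr = np.concatenate([[1.0], sens, [0.0]])
    order = np.argsort(fpr)
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    return TdRocCurve(horizon, thresholds, sens, spec, auc)


def km_curve(outcome: pd.DataFrame, labels=None) -> dict:
    """Kaplan–Meier estimate per group (single group when labels omitted).

    Returns ``{label: DataFrame(time, survival, at_risk)}``.
    """
    t = outcome["time_months"].to_numpy(dtype=float)
    e = outcome["event"].to_numpy(dtype=int)
    labels = np.asarray(["all"] * len(t)) if labels is None else np.asarray(labels)
    if labels.shape[0] != len(t):
        raise ValueError("labels must align with the outcome table")
    curves = {}
    for g in pd.unique(labels):
        m = labels == g
        if e[m].sum() < 1:
            raise ValueError(f"group {g!r} has no events")
        kmf = KaplanMeierFitter()
        kmf.fit(t[m], e[m])
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame({
            "time": sf.index.to_numpy(),
            "survival": sf.iloc[:, 0].to_numpy(),
            "at_risk": kmf.event_table["at_risk"].reindex(sf.index).to_numpy(),
        })
    return curves


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    df: int
    p: float


def log_rank(outcome: pd.DataFrame, labels) -> LogRankResult:
    """Standard (multivariate) log-rank test across the label groups."""
    labels = np.asarray(labels)
    if labels.shape[0] != len(outcome):
        raise ValueError("labels must align with the outcome table")
    if pd.isna(labels).any():
        raise ValueError("unknown (missing) group label")
    res = multivariate_logrank_test(outcome["time_months"], labels,
                                    outcome["event"])
    return LogRankResult(float(res.test_statistic),
                         int(len(np.unique(labels)) - 1), float(res.p_value))
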