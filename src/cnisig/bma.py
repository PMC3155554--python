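"""Bayesian model averaging over Cox models on the selected markers.

Each candidate model (a subset of the covariates) is scored by the BIC of its
Cox partial likelihood, with the number of events as the effective sample
size — the standard choice for censored data, where events rather than
subjects carry the information.  Under a uniform prior over models the
posterior model probability is proportional to exp(−BIC/2).  Models whose
posterior odds against the best model exceed the Occam's-window cutoff are
discarded, the remainder renormalised, and each covariate's posterior effect
probability is the summed posterior of the retained models containing it.

Model search is exhaustive up to ``max_exhaustive`` covariates; beyond that a
stepwise neighbourhood search (add/drop one covariate from any model inside
the window, to a fixpoint) approximates the window contents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._coxph import SurvivalData, breslow_loglik, newton_fit

__all__ = ["BmaConfig", "BmaResult", "bma_posterior_effects", "interpret_posterior"]

_MAX_COVARIATES = 30
_MAX_MODELS = 60_000


@dataclass(frozen=True)
class BmaConfig:
    occam_odds: float = 20.0      # discard models this many times less probable
    max_exhaustive: int = 15
    events_as_n: bool = True      # BIC penalty uses number of events, not n

    def __post_init__(self):
        if self.occam_odds <= 1:
            raise ValueError("Occam's-window odds ratio must exceed 1")


@dataclass
class BmaResult:
    models: pd.DataFrame           # one row per retained model: members, bic, posterior
    effect_probability: pd.Series  # p_j per covariate
    categories: pd.Series          # qualitative interpretation of p_j


def interpret_posterior(p_j: float) -> str:
    """Qualitative evidence category for a posterior effect probability.

    Bins: <50% evidence against; [50, 75) weak; [75, 95) positive;
    [95, 99) strong; ≥99% very strong (lower bounds inclusive).  The source
    rule-of-thumb text leaves a gap between 50 and 59%; the contiguous
    [50, 75) bin is used here.
    """
    if not 0.0 <= p_j <= 1.0:
        raise ValueError("posterior probability must be in [0, 1]")
    if p_j < 0.50:
        return "evidence against"
    if p_j < 0.75:
        return "weak evidence"
    if p_j < 0.95:
        return "positive evidence"
    if p_j < 0.99:
        return "strong evidence"
    return "very strong evidence"


def _model_bic(sd: SurvivalData, X_sorted: np.ndarray, members: tuple,
               log_n: float, cache: dict) -> float:
    if members in cache:
        return cache[members]
    if members:
        _, ll, _ = newton_fit(sd, X_sorted[:, list(members)])
    else:
        ll = breslow_loglik(sd, np.zeros(sd.n))
    bic = -2.0 * ll + len(members) * log_n
    cache[members] = bic
    return bic


def bma_posterior_effects(X: pd.DataFrame, outcome: pd.DataFrame,
                          config: BmaConfig = BmaConfig()) -> BmaResult:
    """Posterior effect probabilities by BIC-weighted model averaging."""
    names = list(X.columns)
    p = len(names)
    if p > _MAX_COVARIATES:
        raise ValueError(
            f"{p} covariates exceed the supported {_MAX_COVARIATES}; this is "
            "a post-selection analysis — reduce the candidate set first")
    time = outcome["time_months"].to_numpy(dtype=float)
    event = outcome["event"].to_numpy(dtype=int)
    sd = SurvivalData(time, event)
    Xs = sd.sort(X.to_numpy(dtype=float))
    log_n = np.log(sd.n_events if config.events_as_n else sd.n)
    window = 2.0 * np.log(config.occam_odds)

    cache: dict[tuple, float] = {}
    if p <= config.max_exhaustive:
        for mask in range(2 ** p):
            members = tuple(j for j in range(p) if mask >> j & 1)
            _model_bic(sd, Xs, members, log_n, cache)
            if len(cache) > _MAX_MODELS:
                raise MemoryError(
                    "model space too large to enumerate; lower max_exhaustive "
                    "to use the Occam's-window stepwise search")
    else:
        seeds = [tuple(), tuple(range(p))] + [(j,) for j in range(p)]
        frontier = set(seeds)
        for m in frontier:
            _model_bic(sd, Xs, m, log_n, cache)
        while frontier:
            best = min(cache.values())
            inside = [m for m in frontier if cache[m] <= best + window]
            frontier = set()
            for m in inside:
                sm = set(m)
                for j in range(p):
                    nb = tuple(sorted(sm ^ {j}))
                    if nb not in cache:
                        _model_bic(sd, Xs, nb, log_n, cache)
                        frontier.add(nb)
            if len(cache) > _MAX_MODELS:
                raise MemoryError(
                    "Occam's-window search exceeded the model budget; raise "
                    "occam_odds to tighten the window")

    members_list = list(cache.keys())
    bics = np.array([cache[m] for m in members_list])
    best = bics.min()
    keep = bics <= best + window
    kept_members = [m for m, k in zip(members_list, keep) if k]
    post = np.exp(-(bics[keep] - best) / 2.0)
    post /= post.sum()

    effect = pd.Series(0.0, index=names)
    for m, pr in zip(kept_members, post):
        for j in m:
            effect.iloc[j] += pr
    effect = effect.clip(0.0, 1.0)

    models = pd.DataFrame({
        "members": [tuple(names[j] for j in m) for m in kept_members],
        "bic": bics[keep],
        "posterior": post,
    }).sort_values("posterior", ascending=False).reset_index(drop=True)
    cats = effect.map(interpret_posterior)
    return BmaResult(models, effect.rename("posterior_effect_probability"),
                     cats.rename("category"))
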