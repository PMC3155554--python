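"""Cox proportional-hazards machinery.

Standard multivariate fits (Efron ties, via lifelines) behind a uniform
:class:`CoxFit` summary; componentwise likelihood boosting for marker
selection from the high-dimensional dose matrix; AIC backwards elimination;
and the random training/test split.

Boosting follows the componentwise likelihood-boosting scheme for Cox models:
at each of ``M`` steps every candidate covariate ``j`` is scored by its
penalized one-step update ``U_j / (I_j + λ)`` around the current linear
predictor (held as an offset), the candidate with the largest second-order
penalized log-likelihood gain ``U_j² / (I_j + λ)`` is updated, and any
mandatory (clinical) covariates are refit unpenalized.  Covariates with a
nonzero coefficient after ``M`` steps form the selected set; dose covariates
enter raw (−1/0/+1), one coefficient per segment, so gain and loss at one
locus show opposing hazard ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from ._coxph import SurvivalData, breslow_loglik, componentwise_score_info, newton_fit

__all__ = [
    "CoxFit",
    "BoostConfig",
    "cox_fit",
    "coxboost_select",
    "backwards_eliminate_aic",
    "split_cohort",
]


@dataclass
class CoxFit:
    """Fitted Cox model summary.

    ``summary`` has one row per covariate with columns ``coef, se, hr,
    hr_lower, hr_upper, p``; degenerate (zero-variance) covariates are kept
    with coef 0 and infinite SE, flagged in ``degenerate``.
    """

    summary: pd.DataFrame
    log_likelihood: float
    n: int
    n_events: int
    ties: str = "efron"
    degenerate: tuple = ()

    @property
    def coefs(self) -> pd.Series:
        return self.summary["coef"]

    @property
    def aic(self) -> float:
        k = int((self.summary["coef"] != 0).sum())
        return -2.0 * self.log_likelihood + 2.0 * k

    def predict_log_hazard(self, X: pd.DataFrame) -> pd.Series:
        X = X[self.summary.index]
        return pd.Series(X.to_numpy(dtype=float) @ self.coefs.to_numpy(),
                         index=X.index, name="log_hazard")


def _check_outcome(outcome: pd.DataFrame):
    time = outcome["time_months"].to_numpy(dtype=float)
    event = outcome["event"].to_numpy(dtype=int)
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    if event.sum() < 1:
        raise ValueError("at least one event is required for a Cox fit")
    return time, event


def _collinear_columns(X: np.ndarray, names) -> list[str]:
    bad = []
    for j in range(1, X.shape[1]):
        sub = X[:, :j]
        coef, res, *_ = np.linalg.lstsq(sub, X[:, j], rcond=None)
        resid = X[:, j] - sub @ coef
        denom = max(np.linalg.norm(X[:, j]), 1.0)
        if np.linalg.norm(resid) / denom < 1e-10:
            bad.append(names[j])
    return bad


def cox_fit(X: pd.DataFrame, outcome: pd.DataFrame, ties: str = "efron") -> CoxFit:
    """Multivariate Cox fit with SEs from the observed information.

    ``ties='efron'`` uses lifelines' Newton–Raphson fit of the Efron partial
    likelihood; ``ties='breslow'`` uses the internal engine.  Zero-variance
    columns are reported with coefficient 0 and infinite SE rather than
    fitted; collinear columns raise a ``ValueError`` naming them.
    """
    time, event = _check_outcome(outcome)
    if len(X) != len(outcome):
        raise ValueError("X and outcome must have equal length")
    names = list(X.columns)
    arr = X.to_numpy(dtype=float)
    variances = arr.var(axis=0)
    degenerate = tuple(n for n, v in zip(names, variances) if v == 0)
    active = [n for n in names if n not in degenerate]
    if active:
        act = X[active].to_numpy(dtype=float)
        if np.linalg.matrix_rank(act - act.mean(axis=0)) < len(active):
            bad = _collinear_columns(act - act.mean(axis=0), active)
            raise ValueError(f"collinear covariates: {bad}")

    if degenerate:
        warnings.warn(f"zero-variance covariates held at beta=0: {degenerate}",
                      RuntimeWarning, stacklevel=2)

    rows = {}
    if not active:
        sd = SurvivalData(time, event)
        ll = breslow_loglik(sd, np.zeros(len(time)))
        for n_ in names:
            rows[n_] = (0.0, np.inf, 1.0, 0.0, np.inf, 1.0)
        summary = pd.DataFrame.from_dict(
            rows, orient="index",
            columns=["coef", "se", "hr", "hr_lower", "hr_upper", "p"])
        return CoxFit(summary.loc[names], ll, len(time), int(event.sum()),
                      ties, degenerate)

    if ties == "efron":
        df = X[active].copy()
        df["__T"] = time
        df["__E"] = event
        cph = CoxPHFitter()
        cph.fit(df, duration_col="__T", event_col="__E")
        beta = cph.params_.reindex(active)
        se = cph.standard_errors_.reindex(active)
        ll = float(cph.log_likelihood_)
    elif ties == "breslow":
        sd = SurvivalData(time, event)
        Xs = sd.sort(X[active].to_numpy(dtype=float))
        b, ll, inv_info = newton_fit(sd, Xs)
        beta = pd.Series(b, index=active)
        se = pd.Series(np.sqrt(np.diag(inv_info)), index=active)
    else:
        raise ValueError(f"unknown ties method {ties!r}")

    z = stats.norm.ppf(0.975)
    for n_ in names:
        if n_ in degenerate:
            rows[n_] = (0.0, np.inf, 1.0, 0.0, np.inf, 1.0)
        else:
            b_, s_ = float(beta[n_]), float(se[n_])
            p = 2 * stats.norm.sf(abs(b_ / s_)) if s_ > 0 else 1.0
            rows[n_] = (b_, s_, np.exp(b_), np.exp(b_ - z * s_),
                        np.exp(b_ + z * s_), p)
    summary = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["coef", "se", "hr", "hr_lower", "hr_upper", "p"]).loc[names]
    return CoxFit(summary, ll, len(time), int(event.sum()), ties, degenerate)


@dataclass(frozen=True)
class BoostConfig:
    """Componentwise boosting settings.

    ``penalty=None`` uses the conventional default of 9 × number of events.
    """

    steps: int = 100
    penalty: float | None = None
    mandatory: tuple = ()

    def __post_init__(self):
        if self.steps < 0:
            raise ValueError("steps must be >= 0")
        if self.penalty is not None and self.penalty <= 0:
            raise ValueError("penalty must be > 0")


@dataclass
class BoostResult:
    coefs: pd.Series            # boosted beta per candidate segment
    mandatory_coefs: pd.Series  # unpenalized clinical coefficients
    selected: list              # candidates with nonzero beta
    loglik_path: np.ndarray     # Breslow log partial likelihood after each step
    penalty: float


def coxboost_select(doses: pd.DataFrame, outcome: pd.DataFrame,
                    clinical_mandatory: pd.DataFrame | None = None,
                    config: BoostConfig = BoostConfig()) -> BoostResult:
    """Componentwise likelihood boosting over the dose matrix.

    Returns the boosted coefficients, the unpenalized mandatory-covariate
    coefficients, the selected (nonzero) segments, and the log partial
    likelihood after each step (non-decreasing).
    """
    time, event = _check_outcome(outcome)
    sd = SurvivalData(time, event)
    lam = config.penalty if config.penalty is not None else 9.0 * sd.n_events

    cand_names = list(doses.columns)
    Xd = sd.sort(doses.to_numpy(dtype=float))
    beta = np.zeros(len(cand_names))

    has_mand = clinical_mandatory is not None and clinical_mandatory.shape[1] > 0
    if has_mand:
        mand_names = list(clinical_mandatory.columns)
        Xm = sd.sort(clinical_mandatory.to_numpy(dtype=float))
        gamma = np.zeros(len(mand_names))
    else:
        mand_names, Xm, gamma = [], None, np.array([])

    path = []
    for _ in range(config.steps):
        if has_mand:
            gamma, _, _ = newton_fit(sd, Xm, offset_sorted=Xd @ beta, beta0=gamma)
        eta = Xd @ beta + (Xm @ gamma if has_mand else 0.0)
        U, I = componentwise_score_info(sd, Xd, eta)
        gain = U ** 2 / (I + lam)   # second-order penalized log-likelihood gain
        j = int(np.argmax(gain))
        beta[j] += U[j] / (I[j] + lam)
        path.append(breslow_loglik(sd, Xd @ beta + (Xm @ gamma if has_mand else 0.0)))

    if has_mand:  # final unpenalized refit against the finished dose predictor
        gamma, ll_final, _ = newton_fit(sd, Xm, offset_sorted=Xd @ beta, beta0=gamma)
        if config.steps == 0:
            path.append(ll_final)

    coefs = pd.Series(beta, index=cand_names, name="boosted_coef")
    selected = [n for n, b in coefs.items() if b != 0.0]
    return BoostResult(coefs, pd.Series(gamma, index=mand_names), selected,
                       np.array(path), lam)


def backwards_eliminate_aic(X_full: pd.DataFrame, outcome: pd.DataFrame,
                            forced: tuple = ()) -> CoxFit:
    """Backwards elimination minimising AIC; ``forced`` covariates never drop."""
    missing = [f for f in forced if f not in X_full.columns]
    if missing:
        raise ValueError(f"forced covariates not in X: {missing}")
    current = list(X_full.columns)
    fit = cox_fit(X_full[current], outcome)
    while True:
        droppable = [c for c in current if c not in forced]
        if not droppable:
            break
        best_aic, best_cols, best_fit = fit.aic, None, None
        for c in droppable:
            cols = [k for k in current if k != c]
            cand = cox_fit(X_full[cols], outcome) if cols else None
            if cand is not None and cand.aic < best_aic:
                best_aic, best_cols, best_fit = cand.aic, cols, cand
        if best_cols is None:
            break
        current, fit = best_cols, best_fit
    return fit


def split_cohort(samples, train_fraction: float = 0.75, seed: int = 0):
    """Random disjoint, exhaustive train/test partition of sample IDs.

    Training size is ``round(n × fraction)`` — e.g. 971 samples at 0.75 give
    728 training and 243 test samples.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    samples = list(samples)
    n = len(samples)
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    n_train = int(round(n * train_fraction))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    train = [samples[i] for i in sorted(perm[:n_train])]
    test = [samples[i] for i in sorted(perm[n_train:])]
    return train, test
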