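"""Risk index and low / no-CNI / high grouping from selected markers.

The per-sample risk index is the inner product of the training-set
coefficients with the dose codes of the selected segments, r_i = Σ_j β_j x_ij.
Groups: samples with no imbalance at any selected marker form the
intermediate "no-CNI" group; among the rest, r > 0 is high risk and r < 0 is
low risk.  A sample whose nonzero doses cancel to exactly r = 0 is assigned
to no-CNI with a warning (the group definitions conflate "index 0" and
"no marker event"; this is the documented tie-break).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .cox_models import cox_fit

__all__ = ["risk_index", "classify_risk", "group_hazards", "GROUPS"]

GROUPS = ("low", "no-CNI", "high")


def risk_index(doses_selected: pd.DataFrame, betas: pd.Series) -> pd.Series:
    """Exact inner product of each sample's dose vector with the coefficients."""
    if set(doses_selected.columns) != set(betas.index):
        missing = set(betas.index) ^ set(doses_selected.columns)
        raise ValueError(f"marker mismatch between doses and betas: {sorted(missing)}")
    X = doses_selected[betas.index].to_numpy(dtype=float)
    return pd.Series(X @ betas.to_numpy(dtype=float),
                     index=doses_selected.index, name="risk_index")


def classify_risk(doses_selected: pd.DataFrame, betas: pd.Series) -> pd.DataFrame:
    """Per-sample risk index, nonzero-marker count, and group label."""
    r = risk_index(doses_selected, betas)
    n_nonzero = (doses_selected[betas.index] != 0).sum(axis=1)
    group = np.where(n_nonzero == 0, "no-CNI",
                     np.where(r > 0, "high", np.where(r < 0, "low", "no-CNI")))
    cancelled = (n_nonzero > 0) & (r == 0)
    if cancelled.any():
        warnings.warn(
            f"{int(cancelled.sum())} sample(s) with nonzero doses but risk "
            "index exactly 0 assigned to no-CNI", RuntimeWarning, stacklevel=2)
    return pd.DataFrame({"risk_index": r, "n_markers_nonzero": n_nonzero,
                         "group": group}, index=doses_selected.index)


def group_summary(classification: pd.DataFrame) -> pd.DataFrame:
    counts = classification["group"].value_counts().reindex(GROUPS, fill_value=0)
    return pd.DataFrame({"n": counts, "fraction": counts / counts.sum()})


def group_hazards(groups, outcome: pd.DataFrame) -> pd.DataFrame:
    """Hazard ratios of high and low risk versus the no-CNI reference.

    Cox fit with two indicator covariates; returns one row per contrast with
    HR, 95% CI and p.
    """
    groups = np.asarray(groups)
    if not np.any(groups == "no-CNI"):
        raise ValueError("empty no-CNI reference group")
    X = pd.DataFrame({
        "high_vs_noCNI": (groups == "high").astype(float),
        "low_vs_noCNI": (groups == "low").astype(float),
    })
    present = [c for c, g in zip(X.columns, ("high", "low"))
               if np.any(groups == g)]
    fit = cox_fit(X[present].reset_index(drop=True),
                  outcome.reset_index(drop=True))
    return fit.summary[["hr", "hr_lower", "hr_upper", "p"]]
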