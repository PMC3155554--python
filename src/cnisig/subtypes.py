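"""Tumor subtype assignment and subtype-specific copy-number frequencies.

Subtypes are approximated from the IHC marker panel plus the array-based
ERBB2 copy number: HER2 if ERBB2 CN exceeds the gain threshold (2.8,
calibrated against clinical IHC scoring by ROC); otherwise ER+ tumours split
on Ki67 at 20% into LUM A (<20%) and LUM B (≥20%); ER−/PR− is TNBC; the
ER−/PR+ combination is not covered by any rule and stays unclassified.
HER2 takes precedence over the luminal split so the categories are mutually
exclusive.

Frequency machinery: recurrent-imbalance flagging at a minimum frequency
(default 10%), and per-segment association tests of dose category × subtype
with a permutation plug-in FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "assign_subtype",
    "assign_subtypes",
    "her2_threshold_roc",
    "recurrent_cnis",
    "subtype_frequency_test",
]

HER2_CN_THRESHOLD = 2.8
KI67_SPLIT = 20.0


def assign_subtype(er: str, pr: str, ki67_pct: float | None, erbb2_cn: float,
                   her2_threshold: float = HER2_CN_THRESHOLD) -> str:
    """Classify one tumour from its marker panel.

    ER/PR are '+' / '-' (positivity = ≥1% staining, upstream of this call).
    Returns one of 'LUM A', 'LUM B', 'HER2', 'TNBC', 'unclassified'.
    """
    if er not in ("+", "-") or pr not in ("+", "-"):
        raise ValueError("ER and PR status must be '+' or '-'")
    if not np.isfinite(erbb2_cn) or erbb2_cn <= 0:
        raise ValueError("ERBB2 copy number must be positive and finite")
    if erbb2_cn > her2_threshold:
        return "HER2"
    if er == "+":
        if ki67_pct is None or not np.isfinite(ki67_pct):
            return "unclassified"  # ER+/HER2− needs Ki67 for the luminal split
        return "LUM A" if ki67_pct < KI67_SPLIT else "LUM B"
    if pr == "-":
        return "TNBC"
    return "unclassified"  # ER−/PR+/HER2−: no printed rule covers it


def assign_subtypes(clinical: pd.DataFrame,
                    her2_threshold: float = HER2_CN_THRESHOLD) -> pd.Series:
    """Vectorised :func:`assign_subtype` over a clinical table.

    Expects columns ``er, pr, ki67_pct, erbb2_cn``.
    """
    out = [assign_subtype(r.er, r.pr,
                          None if pd.isna(r.ki67_pct) else float(r.ki67_pct),
                          float(r.erbb2_cn), her2_threshold)
           for r in clinical.itertuples(index=False)]
    idx = clinical["sample"] if "sample" in clinical else clinical.index
    return pd.Series(out, index=idx, name="subtype")


@dataclass
class ThresholdRoc:
    roc: pd.DataFrame  # threshold, fpr, tpr
    auc: float
    best_threshold: float


def her2_threshold_roc(erbb2_cn, ihc_amplified) -> ThresholdRoc:
    """Empirical ROC of copy number against binarised IHC HER2 status.

    ``ihc_amplified`` is 1 for IHC 3+ (amplified), 0 for 0/1+; equivocal 2+
    cases must be excluded upstream.  The suggested threshold maximises
    Youden's J, ties resolved toward the larger threshold.
    """
    cn = np.asarray(erbb2_cn, dtype=float)
    y = np.asarray(ihc_amplified, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both amplified and non-amplified labels")
    fpr, tpr, thr = roc_curve(y, cn)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())
    # roc_curve thresholds descend; the first maximiser is the largest
    best_threshold = float(thr[best[0]])
    roc = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    return ThresholdRoc(roc, auc, best_threshold)


def recurrent_cnis(doses: pd.DataFrame, min_freq: float = 0.10,
                   labels=None) -> pd.DataFrame:
    """Segments recurrently gained/lost at ≥ ``min_freq`` (inclusive).

    With ``labels`` given, frequencies and flags are computed per group;
    otherwise over all samples (group 'all').  Returns a tidy frame with
    columns ``segment_id, group, direction, frequency, recurrent``.
    """
    labels = np.asarray(["all"] * len(doses)) if labels is None else np.asarray(labels)
    rows = []
    d = doses.to_numpy()
    for g in pd.unique(labels):
        m = labels == g
        gain = (d[m] == 1).mean(axis=0)
        loss = (d[m] == -1).mean(axis=0)
        for seg, fg, fl in zip(doses.columns, gain, loss):
            rows.append((seg, g, "gain", fg, fg >= min_freq))
            rows.append((seg, g, "loss", fl, fl >= min_freq))
    return pd.DataFrame(rows, columns=["segment_id", "group", "direction",
                                       "frequency", "recurrent"])


def _chi2_pvalues(tables: np.ndarray) -> np.ndarray:
    """Vectorised chi-square p for a stack of contingency tables (s, r, c).

    Rows/columns that are empty in a table contribute neither to the statistic
    nor to the degrees of freedom.
    """
    row = tables.sum(axis=2, keepdims=True)
    col = tables.sum(axis=1, keepdims=True)
    n = tables.sum(axis=(1, 2), keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = row * col / n
        cells = np.where(expected > 0, (tables - expected) ** 2 / expected, 0.0)
    stat = cells.sum(axis=(1, 2))
    r_eff = (row.squeeze(2) > 0).sum(axis=1)
    c_eff = (col.squeeze(1) > 0).sum(axis=1)
    df = np.maximum((r_eff - 1) * (c_eff - 1), 0)
    p = np.ones(tables.shape[0])
    ok = df > 0
    p[ok] = stats.chi2.sf(stat[ok], df[ok])
    return p


def _segment_pvalues(dose_onehot: np.ndarray, label_onehot: np.ndarray,
                     fisher_mask: np.ndarray) -> np.ndarray:
    """p-value per segment for dose-category × group association.

    ``dose_onehot``: (segments, 3, n); ``label_onehot``: (n, groups).
    Segments flagged in ``fisher_mask`` (2×2 after dropping empty levels,
    small expected counts) use Fisher's exact test; the rest chi-square.
    """
    tables = np.einsum("sdn,ng->sdg", dose_onehot, label_onehot)
    p = _chi2_pvalues(tables)
    for s in np.flatnonzero(fisher_mask):
        t = tables[s]
        t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
        if t.shape == (2, 2):
            p[s] = stats.fisher_exact(t.astype(int))[1]
    return p


def _fisher_applicable(tables: np.ndarray) -> np.ndarray:
    """2×2 after dropping empty levels, with any expected cell < 5."""
    mask = np.zeros(tables.shape[0], dtype=bool)
    for s, t in enumerate(tables):
        t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
        if t.shape != (2, 2):
            continue
        row = t.sum(axis=1, keepdims=True)
        col = t.sum(axis=0, keepdims=True)
        expected = row * col / t.sum()
        mask[s] = expected.min() < 5
    return mask


def subtype_frequency_test(doses: pd.DataFrame, labels, b_perm: int = 1000,
                           seed: int = 0) -> pd.DataFrame:
    """Per-segment association of dose category with subtype, permutation FDR.

    The observed p-value per segment comes from a chi-square test of the
    (−1/0/+1) × subtype table (Fisher's exact when the collapsed table is 2×2
    with small expected counts).  The null is built by shuffling the subtype
    labels ``b_perm`` times and recomputing all p-values; the plug-in FDR at
    threshold t is (mean permutation count of p ≤ t) / (observed count of
    p ≤ t), evaluated at each observed p and monotonized so that tightening
    the threshold never raises the estimate.
    """
    if b_perm < 100:
        raise ValueError("b_perm must be at least 100")
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least two subtype groups")
    n = len(labels)
    d = doses.to_numpy().T  # (segments, n)
    dose_onehot = np.stack([(d == v).astype(float) for v in (-1, 0, 1)], axis=1)
    gidx = {g: k for k, g in enumerate(groups)}
    lab_codes = np.array([gidx[g] for g in labels])
    eye = np.eye(len(groups))

    tables_obs = np.einsum("sdn,ng->sdg", dose_onehot, eye[lab_codes])
    fisher_mask = _fisher_applicable(tables_obs)
    p_obs = _segment_pvalues(dose_onehot, eye[lab_codes], fisher_mask)

    rng = np.random.default_rng(seed)
    null_counts = np.zeros(len(p_obs))
    order = np.argsort(p_obs)
    sorted_p = p_obs[order]
    for _ in range(b_perm):
        perm = rng.permutation(lab_codes)
        p_null = _segment_pvalues(dose_onehot, eye[perm], fisher_mask)
        null_counts += np.searchsorted(np.sort(p_null), sorted_p, side="right")
    mean_null = null_counts / b_perm
    obs_counts = np.arange(1, len(sorted_p) + 1)
    raw_fdr = np.minimum(mean_null / obs_counts, 1.0)
    # monotone: a tighter p threshold can only lower the estimate
    monot = np.minimum.accumulate(raw_fdr[::-1])[::-1]
    fdr = np.empty_like(monot)
    fdr[order] = monot

    freq = {g: {} for g in groups}
    for k, g in enumerate(groups):
        m = lab_codes == k
        freq[g]["gain"] = (d[:, m] == 1).mean(axis=1)
        freq[g]["loss"] = (d[:, m] == -1).mean(axis=1)

    out = pd.DataFrame({"segment_id": doses.columns, "p": p_obs, "fdr": fdr,
                        "test": np.where(fisher_mask, "fisher", "chi2")})
    for g in groups:
        out[f"gain_freq[{g}]"] = freq[g]["gain"]
        out[f"loss_freq[{g}]"] = freq[g]["loss"]
    return out
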