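"""Copy-number segmentation: running medians, CBS, calls, common grid.

The reduction stage collapses consecutive probes into running-median bins
(default groups of 25).  Each sample × chromosome is then segmented with
circular binary segmentation (CBS): the arc of bins maximising the two-sample
t statistic between inside and outside means is tested against a permutation
null (significance ``alpha``), and accepted splits are recursed on.  Segment
means are called as gain (+1), neutral (0) or loss (−1) against fixed
linear-scale thresholds (2.5 / 1.5 for one copy gained / lost).  Finally the
per-sample change-points are unioned into a common genome-wide grid, and
adjacent grid segments whose calls agree in at least 99.5% of samples are
recombined, yielding the common segments whose dose codes feed the survival
models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SegmentationParams",
    "ReducedMatrix",
    "reduce_running_median",
    "max_arc_stat",
    "cbs_segment",
    "call_segment",
    "segment_profiles",
    "build_common_grid",
]


@dataclass(frozen=True)
class SegmentationParams:
    group_size: int = 25
    alpha: float = 0.01
    n_permutations: int = 1000
    min_seg_bins: int = 3
    gain_threshold: float = 2.5
    loss_threshold: float = 1.5
    agreement: float = 0.995
    keep_remainder_bin: bool = True
    baseline: float = 2.0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not self.loss_threshold < self.baseline < self.gain_threshold:
            raise ValueError("need loss_threshold < baseline < gain_threshold")
        if not 0.5 < self.agreement <= 1:
            raise ValueError("agreement must be in (0.5, 1]")


class ReducedMatrix:
    """Running-median bins: a bin table plus samples × bins values."""

    def __init__(self, bins: pd.DataFrame, values: pd.DataFrame):
        self.bins = bins.reset_index(drop=True)   # bin_id, chrom, start_pos, stop_pos, n_probes
        self.values = values                      # index: samples, columns: bin_id

    def chrom_bin_index(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.bins["chrom"] == chrom).to_numpy())

    @property
    def chromosomes(self):
        return list(dict.fromkeys(self.bins["chrom"]))


def reduce_running_median(pm, group_size: int = 25,
                          keep_remainder: bool = True) -> ReducedMatrix:
    """Median of consecutive probe groups, never spanning chromosomes.

    A trailing group shorter than ``group_size`` is kept as its own bin by
    default (preserves genome coverage); set ``keep_remainder=False`` to drop
    it, giving exactly ``floor(n_probes / group_size)`` bins per chromosome.
    """
    bins = []
    bin_values = []
    vals = pm.values.to_numpy()
    for chrom in pm.chromosomes:
        idx = np.flatnonzero((pm.probes["chrom"] == chrom).to_numpy())
        if len(idx) < group_size:
            raise ValueError(
                f"chromosome {chrom} has {len(idx)} probes, fewer than the "
                f"group size {group_size}")
        pos = pm.probes["pos"].to_numpy()[idx]
        n_full = len(idx) // group_size
        edges = [(k * group_size, (k + 1) * group_size) for k in range(n_full)]
        rem = len(idx) - n_full * group_size
        if rem and keep_remainder:
            edges.append((n_full * group_size, len(idx)))
        for k, (a, b) in enumerate(edges):
            bins.append((f"{chrom}_b{k:05d}", chrom, int(pos[a]), int(pos[b - 1]), b - a))
            bin_values.append(np.median(vals[:, idx[a:b]], axis=1))
    bin_df = pd.DataFrame(bins, columns=["bin_id", "chrom", "start_pos",
                                         "stop_pos", "n_probes"])
    values = pd.DataFrame(np.column_stack(bin_values), index=pm.values.index,
                          columns=bin_df["bin_id"])
    return ReducedMatrix(bin_df, values)


def max_arc_stat(x: np.ndarray, min_seg: int = 3):
    """Best arc [i, j) of ``x`` by the two-sample t statistic, exhaustively.

    Returns ``(stat, i, j)`` with ``stat = |mean_in − mean_out| / (s·sqrt(1/k
    + 1/(n−k)))`` maximised over all arcs with both sides ≥ ``min_seg`` bins;
    ``s`` is the sample SD of the whole span.  ``(0.0, None, None)`` when the
    span is constant or too short.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2 * min_seg:
        return 0.0, None, None
    s = x.std(ddof=1)
    if s == 0 or not np.isfinite(s):
        return 0.0, None, None
    c = np.concatenate([[0.0], np.cumsum(x)])
    T = c[-1]
    # S[i, j] = sum of x[i:j]
    S = c[None, :] - c[:, None]
    i_idx, j_idx = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
    k = j_idx - i_idx
    valid = (k >= min_seg) & (n - k >= min_seg)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(S / k - (T - S) / (n - k)) / (s * np.sqrt(1.0 / k + 1.0 / (n - k)))
    t[~valid] = -np.inf
    flat = int(np.argmax(t))
    i, j = divmod(flat, n + 1)
    return float(t[i, j]), int(i), int(j)


def _perm_max_stats(x: np.ndarray, n_perm: int, min_seg: int, rng) -> np.ndarray:
    """Max arc statistic for ``n_perm`` within-span permutations of ``x``."""
    n = x.size
    s = x.std(ddof=1)
    T = x.sum()
    perms = rng.permuted(np.broadcast_to(x, (n_perm, n)), axis=1)
    c = np.concatenate([np.zeros((n_perm, 1)), np.cumsum(perms, axis=1)], axis=1)
    best = np.zeros(n_perm)
    for k in range(min_seg, n - min_seg + 1):
        S = c[:, k:] - c[:, :-k]
        denom = s * np.sqrt(1.0 / k + 1.0 / (n - k))
        t = np.abs(S / k - (T - S) / (n - k)) / denom
        np.maximum(best, t.max(axis=1), out=best)
    return best


def _perm_pvalue_exceeds(x, observed, params, rng) -> bool:
    """True if the permutation p-value is below alpha (chunked, early stop)."""
    B = params.n_permutations
    allowed = params.alpha * (B + 1) - 1  # max exceedances compatible with p < alpha
    exceed = 0
    done = 0
    chunk = max(100, int(allowed) + 1)
    while done < B:
        b = min(chunk, B - done)
        stats = _perm_max_stats(x, b, params.min_seg_bins, rng)
        exceed += int(np.sum(stats >= observed))
        done += b
        if exceed > allowed:
            return False
    p = (1 + exceed) / (B + 1)
    return p < params.alpha


def cbs_segment(values: np.ndarray, params: SegmentationParams,
                rng=None) -> list[int]:
    """Change-points of one sample's binned chromosome by recursive CBS.

    Returns sorted interior boundaries ``b`` (splits between ``values[:b]``
    and ``values[b:]``).  Permutation randomness comes from ``rng`` (fresh
    default generator when omitted).
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in segmentation input")
    rng = rng if rng is not None else np.random.default_rng()
    breaks: list[int] = []

    def recurse(lo: int, hi: int):
        span = x[lo:hi]
        stat, i, j = max_arc_stat(span, params.min_seg_bins)
        if i is None or stat <= 0:
            return
        if not _perm_pvalue_exceeds(span, stat, params, rng):
            return
        cuts = [b for b in (i, j) if 0 < b < hi - lo]
        pieces = [lo] + [lo + b for b in cuts] + [hi]
        for b in cuts:
            breaks.append(lo + b)
        for a, b in zip(pieces, pieces[1:]):
            recurse(a, b)

    recurse(0, x.size)
    return sorted(breaks)


def call_segment(mean_cn: float, params: SegmentationParams) -> int:
    """Dose call for a segment mean: +1 gain, −1 loss, 0 neutral (inclusive)."""
    if not np.isfinite(mean_cn):
        raise ValueError("segment mean must be finite")
    if mean_cn >= params.gain_threshold:
        return 1
    if mean_cn <= params.loss_threshold:
        return -1
    return 0


def segment_profiles(reduced: ReducedMatrix, params: SegmentationParams,
                     seed: int = 0) -> pd.DataFrame:
    """Segment every sample × chromosome; returns a tidy segment table.

    Columns: sample, chrom, start_bin, stop_bin (inclusive, chromosome-local),
    n_bins, seg_mean, call.  Each (sample, chromosome) pair gets its own
    permutation stream keyed by index, so results do not depend on execution
    order.
    """
    rows = []
    samples = list(reduced.values.index)
    vals = reduced.values.to_numpy()
    for ci, chrom in enumerate(reduced.chromosomes):
        idx = reduced.chrom_bin_index(chrom)
        for si, sample in enumerate(samples):
            x = vals[si, idx]
            rng = np.random.default_rng(np.random.SeedSequence((seed, si, ci)))
            breaks = cbs_segment(x, params, rng)
            bounds = [0] + breaks + [len(idx)]
            for a, b in zip(bounds, bounds[1:]):
                seg_mean = float(x[a:b].mean())
                rows.append((sample, chrom, a, b - 1, b - a, seg_mean,
                             call_segment(seg_mean, params)))
    return pd.DataFrame(rows, columns=["sample", "chrom", "start_bin",
                                       "stop_bin", "n_bins", "seg_mean", "call"])


def _merge_pass(doses: np.ndarray, seg_meta: list, agreement: float):
    """One left-to-right merge sweep; returns (doses, meta, changed)."""
    n_samples = doses.shape[0]
    out_doses = []
    out_meta = []
    changed = False
    k = 0
    cur_d = doses[:, 0].copy()
    cur_m = dict(seg_meta[0])
    for k in range(1, doses.shape[1]):
        nxt_d = doses[:, k]
        nxt_m = seg_meta[k]
        same_chrom = nxt_m["chrom"] == cur_m["chrom"]
        agree = np.mean(cur_d == nxt_d) if same_chrom else 0.0
        if same_chrom and agree >= agreement:
            # merged call per sample: the larger constituent wins, ties → left
            if nxt_m["n_bins"] > cur_m["n_bins"]:
                merged = nxt_d.copy()
            else:
                merged = cur_d
            cur_d = merged
            cur_m = {"chrom": cur_m["chrom"],
                     "start_bin": cur_m["start_bin"],
                     "stop_bin": nxt_m["stop_bin"],
                     "n_bins": cur_m["n_bins"] + nxt_m["n_bins"]}
            changed = True
        else:
            out_doses.append(cur_d)
            out_meta.append(cur_m)
            cur_d = nxt_d.copy()
            cur_m = dict(nxt_m)
    out_doses.append(cur_d)
    out_meta.append(cur_m)
    return np.column_stack(out_doses), out_meta, changed


def build_common_grid(profiles: pd.DataFrame, reduced: ReducedMatrix,
                      params: SegmentationParams):
    """Union the per-sample change-points and recombine concordant segments.

    Returns ``(grid, dose_matrix)``: ``grid`` is a DataFrame of common
    segments (segment_id, chrom, start_bin, stop_bin, start_pos, stop_pos,
    n_bins) partitioning each chromosome's bins; ``dose_matrix`` is samples ×
    segments with entries in {−1, 0, +1}.  Adjacent segments are merged while
    their per-sample calls agree in at least ``params.agreement`` of samples
    (left-to-right sweeps to a fixpoint); a merged segment inherits, per
    sample, the call of its larger constituent (ties favour the left).
    """
    if profiles.empty:
        raise ValueError("no segment profiles supplied")
    samples = list(reduced.values.index)
    seg_meta: list[dict] = []
    dose_cols: list[np.ndarray] = []

    for chrom in reduced.chromosomes:
        n_bins = len(reduced.chrom_bin_index(chrom))
        sub = profiles[profiles["chrom"] == chrom]
        cuts = sorted(set(sub["start_bin"]) | {n_bins})
        cuts = [c for c in cuts if 0 < c < n_bins]
        bounds = [0] + cuts + [n_bins]
        # per-sample call for each initial grid cell = call of enclosing segment
        call_per_bin = np.zeros((len(samples), n_bins), dtype=int)
        sidx = {s: i for i, s in enumerate(samples)}
        for row in sub.itertuples(index=False):
            call_per_bin[sidx[row.sample], row.start_bin:row.stop_bin + 1] = row.call
        for a, b in zip(bounds, bounds[1:]):
            seg_meta.append({"chrom": chrom, "start_bin": a, "stop_bin": b - 1,
                             "n_bins": b - a})
            dose_cols.append(call_per_bin[:, a])  # constant across the cell

    doses = np.column_stack(dose_cols)
    changed = True
    while changed and doses.shape[1] > 1:
        doses, seg_meta, changed = _merge_pass(doses, seg_meta, params.agreement)

    bins = reduced.bins
    rows = []
    for k, m in enumerate(seg_meta):
        idx = reduced.chrom_bin_index(m["chrom"])
        rows.append((f"seg{k:04d}", m["chrom"], m["start_bin"], m["stop_bin"],
                     int(bins["start_pos"].iloc[idx[m["start_bin"]]]),
                     int(bins["stop_pos"].iloc[idx[m["stop_bin"]]]),
                     m["n_bins"]))
    grid = pd.DataFrame(rows, columns=["segment_id", "chrom", "start_bin",
                                       "stop_bin", "start_pos", "stop_pos",
                                       "n_bins"])
    dose_matrix = pd.DataFrame(doses, index=samples, columns=grid["segment_id"])
    return grid, dose_matrix
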