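"""Segmentation: running medians, CBS change-points, calls, common grid."""

import numpy as np
import pandas as pd
import pytest

from cnisig.segmentation import (ReducedMatrix, SegmentationParams,
                                 build_common_grid, call_segment, cbs_segment,
                                 max_arc_stat, reduce_running_median,
                                 segment_profiles)
from cnisig.simulate import ProbeMatrix

PARAMS = SegmentationParams()


def _probe_matrix(values_by_chrom, spacing=1000):
    """Build a ProbeMatrix from {chrom: (n_samples, n_probes) array}."""
    frames, cols = [], []
    for chrom, vals in values_by_chrom.items():
        n = vals.shape[1]
        frames.append(pd.DataFrame({
            "probe_id": [f"{chrom}_p{i:05d}" for i in range(n)],
            "chrom": chrom, "pos": 1 + spacing * np.arange(n)}))
        cols.append(vals)
    probes = pd.concat(frames, ignore_index=True)
    values = pd.DataFrame(np.concatenate(cols, axis=1),
                          index=[f"S{i}" for i in range(cols[0].shape[0])],
                          columns=probes["probe_id"])
    return ProbeMatrix(probes, values)


class TestRunningMedian:
    def test_constant_input_is_preserved(self):
        pm = _probe_matrix({"chr1": np.full((3, 75), 2.0)})
        red = reduce_running_median(pm, 25)
        assert np.allclose(red.values.to_numpy(), 2.0)
        assert len(red.bins) == 3

    def test_single_outlier_does_not_move_the_bin_median(self):
        vals = np.full((1, 25), 2.0)
        vals[0, 2] = 100.0
        vals[0, 5] = 1.0
        pm = _probe_matrix({"chr1": np.tile(vals, (1, 2))})
        red = reduce_running_median(pm, 25)
        assert np.allclose(red.values.to_numpy(), 2.0)

    def test_remainder_probes_form_short_final_bin_or_are_dropped(self):
        pm = _probe_matrix({"chr1": np.full((2, 130), 2.0)})
        kept = reduce_running_median(pm, 25, keep_remainder=True)
        dropped = reduce_running_median(pm, 25, keep_remainder=False)
        assert len(kept.bins) == 6 and kept.bins["n_probes"].iloc[-1] == 5
        assert len(dropped.bins) == 5
        # 330,000 probes in groups of 25 would give floor(330000/25) = 13,200
        assert 330_000 // 25 == 13_200

    def test_chromosome_shorter_than_group_size_is_rejected_by_name(self):
        pm = _probe_matrix({"chr1": np.full((1, 60), 2.0)})
        with pytest.raises(ValueError, match="chr1"):
            reduce_running_median(pm, 100)

    def test_bins_never_span_chromosomes(self):
        pm = _probe_matrix({"chr1": np.full((1, 60), 2.0),
                            "chr2": np.full((1, 60), 3.0)})
        red = reduce_running_median(pm, 25)
        assert list(red.bins["chrom"]) == ["chr1", "chr1", "chr1",
                                           "chr2", "chr2", "chr2"]


def _brute_force_arc(x, min_seg):
    """Independent O(n^2) enumeration of the arc t statistic."""
    x = np.asarray(x, float)
    n = len(x)
    s = x.std(ddof=1)
    best = (-np.inf, None, None)
    for i in range(n + 1):
        for j in range(i + 1, n + 1):
            k = j - i
            if k < min_seg or n - k < min_seg:
                continue
            inside = x[i:j].mean()
            outside = (x.sum() - x[i:j].sum()) / (n - k)
            t = abs(inside - outside) / (s * np.sqrt(1 / k + 1 / (n - k)))
            if t > best[0]:
                best = (t, i, j)
    return best


class TestCbs:
    def test_max_arc_matches_exhaustive_enumeration_on_length_30(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.normal(2.0, 0.3, 30)
            x[10:20] += rng.choice([0.0, 1.0])
            stat, i, j = max_arc_stat(x, min_seg=3)
            bstat, bi, bj = _brute_force_arc(x, 3)
            assert stat == pytest.approx(bstat, abs=1e-10)
            assert (i, j) == (bi, bj)

    def test_flat_sequence_has_no_change_points(self):
        assert cbs_segment(np.full(100, 2.0), PARAMS) == []

    def test_planted_step_recovered_within_one_bin(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(2.0, 0.1, 100), rng.normal(3.0, 0.1, 100)])
        breaks = cbs_segment(x, PARAMS, rng=np.random.default_rng(2))
        assert len(breaks) == 1
        assert abs(breaks[0] - 100) <= 1

    def test_non_finite_input_is_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            cbs_segment(np.array([1.0, np.nan] * 10), PARAMS)

    def test_pure_noise_rarely_splits_at_alpha(self):
        rng = np.random.default_rng(3)
        n_split = sum(bool(cbs_segment(rng.normal(2, 0.15, 80), PARAMS,
                                       rng=np.random.default_rng(100 + k)))
                      for k in range(20))
        assert n_split <= 2


class TestCalling:
    @pytest.mark.parametrize("mean_cn,expected", [
        (2.6, 1), (2.5, 1), (2.0, 0), (2.49, 0), (1.51, 0), (1.5, -1), (1.0, -1),
    ])
    def test_threshold_calls_are_inclusive(self, mean_cn, expected):
        assert call_segment(mean_cn, PARAMS) == expected

    def test_non_finite_mean_is_rejected(self):
        with pytest.raises(ValueError):
            call_segment(np.nan, PARAMS)


def _reduced_from_calls(n_bins):
    bins = pd.DataFrame({
        "bin_id": [f"chr1_b{i:05d}" for i in range(n_bins)],
        "chrom": "chr1",
        "start_pos": 1 + 25_000 * np.arange(n_bins),
        "stop_pos": 24_001 + 25_000 * np.arange(n_bins),
        "n_probes": 25,
    })
    return bins


class TestCommonGrid:
    def _make(self, n_samples, n_bins, profile_rows):
        bins = _reduced_from_calls(n_bins)
        values = pd.DataFrame(np.full((n_samples, n_bins), 2.0),
                              index=[f"S{i:04d}" for i in range(n_samples)],
                              columns=bins["bin_id"])
        return ReducedMatrix(bins, values), pd.DataFrame(
            profile_rows, columns=["sample", "chrom", "start_bin", "stop_bin",
                                   "n_bins", "seg_mean", "call"])

    def test_identical_call_columns_merge_into_one_segment(self):
        rows = []
        for i in range(4):
            s = f"S{i:04d}"
            rows += [(s, "chr1", 0, 4, 5, 3.0, 1), (s, "chr1", 5, 9, 5, 3.0, 1)]
        red, prof = self._make(4, 10, rows)
        grid, doses = build_common_grid(prof, red, PARAMS)
        assert len(grid) == 1
        assert (doses.to_numpy() == 1).all()

    @pytest.mark.parametrize("n_differing,expect_merged", [(6, False), (5, True)])
    def test_recombination_threshold_at_99_5_percent(self, n_differing,
                                                     expect_merged):
        n = 1000
        rows = []
        for i in range(n):
            s = f"S{i:04d}"
            if i < n_differing:  # change-point: neutral then gain
                rows += [(s, "chr1", 0, 4, 5, 2.0, 0),
                         (s, "chr1", 5, 9, 5, 3.0, 1)]
            else:
                rows += [(s, "chr1", 0, 9, 10, 3.0, 1)]
        red, prof = self._make(n, 10, rows)
        grid, doses = build_common_grid(prof, red, PARAMS)
        assert (len(grid) == 1) == expect_merged

    def test_merged_dose_comes_from_larger_constituent(self):
        rows = []
        for i in range(10):
            s = f"S{i:04d}"
            # 3-bin piece called gain, 7-bin piece called neutral; one sample
            # disagrees so the initial grid keeps the cut, then merges
            if i == 0:
                rows += [(s, "chr1", 0, 2, 3, 3.0, 1),
                         (s, "chr1", 3, 9, 7, 2.0, 0)]
            else:
                rows += [(s, "chr1", 0, 9, 10, 2.0, 0)]
        red, prof = self._make(10, 10, rows)
        params = SegmentationParams(agreement=0.9)
        grid, doses = build_common_grid(prof, red, params)
        assert len(grid) == 1
        assert doses.iloc[0, 0] == 0  # larger (7-bin) constituent wins

    def test_raising_agreement_never_reduces_segment_count(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(50):
            s = f"S{i:04d}"
            cut = rng.integers(3, 8)
            call = int(rng.integers(0, 2))
            rows += [(s, "chr1", 0, cut - 1, cut, 2.0 + call, call),
                     (s, "chr1", cut, 9, 10 - cut, 2.0, 0)]
        red, prof = self._make(50, 10, rows)
        counts = []
        for agreement in (0.6, 0.8, 0.95, 1.0):
            grid, _ = build_common_grid(prof, red,
                                        SegmentationParams(agreement=agreement))
            counts.append(len(grid))
        assert counts == sorted(counts)

    def test_empty_profile_list_is_rejected(self):
        red, prof = self._make(1, 10, [("S0000", "chr1", 0, 9, 10, 2.0, 0)])
        with pytest.raises(ValueError):
            build_common_grid(prof.iloc[:0], red, PARAMS)


class TestEndToEndRecovery:
    def test_noiseless_cohort_recovers_planted_events_exactly(self,
                                                              noiseless_cohort):
        pm, truth, clinical, survival, cfg = noiseless_cohort
        red = reduce_running_median(pm, 25)
        prof = segment_profiles(red, PARAMS, seed=1)
        grid, doses = build_common_grid(prof, red, PARAMS)
        # chr1 event spans probes 125-249 = bins 5-9; chr2 event bins 10-14
        spans = {"gA": ("chr1", 5, 9), "lB": ("chr2", 10, 14)}
        for name, (chrom, b0, b1) in spans.items():
            hit = grid[(grid["chrom"] == chrom) & (grid["start_bin"] == b0)
                       & (grid["stop_bin"] == b1)]
            assert len(hit) == 1, f"event {name} not an exact grid segment"
            seg_id = hit["segment_id"].iloc[0]
            assert np.array_equal(doses[seg_id].to_numpy(),
                                  truth.doses[name].to_numpy())

    def test_grid_partitions_every_chromosome(self, noiseless_cohort):
        pm, *_ = noiseless_cohort
        red = reduce_running_median(pm, 25)
        prof = segment_profiles(red, PARAMS, seed=1)
        grid, _ = build_common_grid(prof, red, PARAMS)
        for chrom in red.chromosomes:
            sub = grid[grid["chrom"] == chrom].sort_values("start_bin")
            n_bins = len(red.chrom_bin_index(chrom))
            assert sub["start_bin"].iloc[0] == 0
            assert sub["stop_bin"].iloc[-1] == n_bins - 1
            assert (sub["start_bin"].iloc[1:].to_numpy()
                    == sub["stop_bin"].iloc[:-1].to_numpy() + 1).all()
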