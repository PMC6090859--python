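"""Unit tests for diel interpolation, Z-scoring and shift classification."""

import numpy as np
import pytest

from camrewire import diel, simulate
from camrewire.clades import OrthologGroup
from camrewire.diel import (
    AGAVE_GRID,
    ARABIDOPSIS_GRID,
    COMMON_GRID,
    ConstantSeriesError,
    DielPair,
    DielSeries,
    classify_shift,
    cluster_pairs,
    filter_expressed,
    interpolate_to_grid,
    pair_orthologs,
    peak_phase,
    zscore,
)

import pandas as pd


def _series(times, values, gene="g", species="cam"):
    return DielSeries(gene, species, tuple(times), tuple(values))


def _cosine(grid, peak, amplitude=1.0):
    t = np.asarray(grid, float)
    return _series(t, amplitude * np.cos(2 * np.pi * (t - peak) / 24.0))


class TestFilterExpressed:
    def test_abundant_gene_kept(self):
        m = pd.DataFrame([[5.0] * 15], index=["g1"])
        assert list(filter_expressed(m).index) == ["g1"]

    def test_gene_detected_in_too_few_samples_removed(self):
        row = [9.0, 9.0, 9.0] + [0.0] * 12
        m = pd.DataFrame([row], index=["g1"])
        assert filter_expressed(m).empty

    def test_low_mean_removed_and_empty_passthrough(self):
        m = pd.DataFrame([[1.0] * 15], index=["g1"])
        assert filter_expressed(m).empty
        assert filter_expressed(pd.DataFrame()).empty


class TestInterpolation:
    def test_exact_at_original_sample_times(self):
        s = _cosine(AGAVE_GRID, 15.0)
        out = interpolate_to_grid(s)
        for t, v in zip(s.times, s.values):
            i = COMMON_GRID.index(t)
            assert out.values[i] == pytest.approx(v, abs=1e-12)

    def test_linear_series_reproduced_away_from_periodic_wrap(self):
        t = np.asarray(AGAVE_GRID)
        s = _series(t, 2.0 * t + 1.0)
        out = interpolate_to_grid(s)
        for q in (4.0, 8.0, 16.0):  # interior points, not wrap-adjacent
            i = COMMON_GRID.index(q)
            assert out.values[i] == pytest.approx(2.0 * q + 1.0, abs=1e-9)

    def test_cosine_off_grid_within_tolerance(self):
        out = interpolate_to_grid(_cosine(AGAVE_GRID, 15.0))
        i = COMMON_GRID.index(16.0)
        assert abs(out.values[i] - np.cos(2 * np.pi * (16 - 15) / 24.0)) < 0.05

    def test_no_overshoot_beyond_local_extremes(self):
        s = _cosine(AGAVE_GRID, 15.0)
        out = interpolate_to_grid(s)
        assert max(out.values) <= max(s.values) + 1e-12
        assert min(out.values) >= min(s.values) - 1e-12

    def test_duplicate_period_endpoint_collapsed(self):
        t = np.asarray(ARABIDOPSIS_GRID)  # includes the 24 h point
        v = np.cos(2 * np.pi * (t - 8.0) / 24.0)
        with_24 = interpolate_to_grid(_series(t, v))
        without_24 = interpolate_to_grid(_series(t[:-1], v[:-1]))
        assert with_24.values == pytest.approx(without_24.values, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            interpolate_to_grid(_series([0.0, 8.0, 16.0], [1.0, 2.0, 3.0]))


class TestZscore:
    def test_mean_zero_sd_one(self):
        z = zscore(_series([0.0, 6.0, 12.0], [1.0, 2.0, 3.0]))
        v = np.asarray(z.values)
        assert v.mean() == pytest.approx(0.0, abs=1e-12)
        assert v.std() == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self):
        z1 = zscore(_cosine(AGAVE_GRID, 9.0))
        z2 = zscore(z1)
        assert np.allclose(z1.values, z2.values, atol=1e-12)

    def test_constant_series_flagged(self):
        with pytest.raises(ConstantSeriesError):
            zscore(_series([0.0, 6.0, 12.0], [2.0, 2.0, 2.0]))


class TestPeakPhase:
    def test_cosine_peak_and_bin(self):
        assert peak_phase(_cosine(COMMON_GRID, 15.0)) == (15.0, "early_night")

    def test_boundary_zero_is_morning(self):
        assert peak_phase(_cosine(COMMON_GRID, 0.0)) == (0.0, "morning")

    def test_tie_broken_by_earliest_time(self):
        v = [0.0] * len(COMMON_GRID)
        v[COMMON_GRID.index(3.0)] = 1.0
        v[COMMON_GRID.index(15.0)] = 1.0
        assert peak_phase(_series(COMMON_GRID, v)) == (3.0, "morning")


class TestClassifyShift:
    def _pair(self, peak_a, peak_b):
        za = zscore(interpolate_to_grid(_cosine(AGAVE_GRID, peak_a)))
        zb = zscore(interpolate_to_grid(_cosine(ARABIDOPSIS_GRID, peak_b)))
        return DielPair("p", za, zb)

    @pytest.mark.parametrize(
        "peak_a,peak_b,expected",
        [
            (15.0, 3.0, "morning_to_night"),
            (20.0, 8.0, "afternoon_to_night"),
            (8.0, 8.0, "none"),
            (3.0, 15.0, "none"),  # reversed direction is not a CAM-style shift
        ],
    )
    def test_rule_based_classes(self, peak_a, peak_b, expected):
        assert classify_shift(self._pair(peak_a, peak_b)).shift_class == expected

    def test_constant_series_propagates_none_with_reason(self):
        za = zscore(interpolate_to_grid(_cosine(AGAVE_GRID, 15.0)))
        flat = _series(COMMON_GRID, [1.0] * len(COMMON_GRID))
        call = classify_shift(DielPair("p", za, flat))
        assert call.shift_class == "none"
        assert "constant" in call.reason

    def test_invariant_to_monotone_transform_of_raw_series(self):
        raw_a = _cosine(AGAVE_GRID, 15.0)
        raw_b = _cosine(ARABIDOPSIS_GRID, 3.0)

        def warp(s):
            return _series(s.times, np.exp(np.asarray(s.values)), s.gene_id, s.species)

        def call(sa, sb):
            return classify_shift(
                DielPair(
                    "p",
                    zscore(interpolate_to_grid(sa)),
                    zscore(interpolate_to_grid(sb)),
                )
            )

        plain, warped = call(raw_a, raw_b), call(warp(raw_a), warp(raw_b))
        assert plain.shift_class == warped.shift_class == "morning_to_night"
        assert plain.bin_a == warped.bin_a
        assert plain.bin_b == warped.bin_b


class TestPairOrthologs:
    GROUPS = [
        OrthologGroup("G1", {"aam": ("a1",), "ath": ("t1",)}),
        OrthologGroup("G2", {"aam": ("a2",), "ath": ("t2",)}),
    ]

    def test_comember_pair_kept(self):
        kept, report = pair_orthologs([("a1", "t1")], self.GROUPS)
        assert kept == [("a1", "t1")]
        assert report == []

    def test_cross_group_pair_dropped(self):
        kept, report = pair_orthologs([("a1", "t2")], self.GROUPS)
        assert kept == []
        assert any("no shared ortholog group" in r for r in report)

    def test_conflicting_pairs_rejected_with_report(self):
        groups = [OrthologGroup("G1", {"aam": ("a1",), "ath": ("t1", "t2")})]
        kept, report = pair_orthologs([("a1", "t1"), ("a1", "t2")], groups)
        assert kept == []
        assert sum("conflicting" in r for r in report) == 2

    def test_empty_input(self):
        assert pair_orthologs([], self.GROUPS) == ([], [])


class TestClusterPairs:
    def _pair(self, peak_a, peak_b, pair_id, seed):
        truth = simulate.DielTruth(pair_id, peak_a, peak_b, noise_sd=0.1)
        sa, sb = simulate.simulate_diel_pair(truth, seed=seed)
        return DielPair(
            pair_id,
            zscore(interpolate_to_grid(sa)),
            zscore(interpolate_to_grid(sb)),
        )

    def test_identical_profiles_merge_at_height_zero(self):
        za = zscore(interpolate_to_grid(_cosine(AGAVE_GRID, 15.0)))
        zb = zscore(interpolate_to_grid(_cosine(ARABIDOPSIS_GRID, 3.0)))
        p = DielPair("p", za, zb)
        labels, Z = cluster_pairs([p, p], k=2)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_single_pair_single_cluster(self):
        p = self._pair(15.0, 3.0, "p", 0)
        labels, _ = cluster_pairs([p], k=1)
        assert list(labels) == [1]

    def test_recovers_planted_shift_partition(self):
        """k=2 cut separates 12 h-shifted from unshifted pairs at low noise."""
        exact = 0
        n_reps = 20
        for rep in range(n_reps):
            pairs, truth = [], []
            for i in range(10):
                pairs.append(self._pair(15.0, 3.0, f"s{i}", seed=100 * rep + i))
                truth.append(0)
            for i in range(10):
                pairs.append(self._pair(3.0, 3.0, f"u{i}", seed=100 * rep + 50 + i))
                truth.append(1)
            labels, _ = cluster_pairs(pairs, k=2)
            split = {}
            for lab, t in zip(labels, truth):
                split.setdefault(t, set()).add(lab)
            exact += (
                len(split[0]) == 1 and len(split[1]) == 1 and split[0] != split[1]
            )
        assert exact >= int(0.95 * n_reps)
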