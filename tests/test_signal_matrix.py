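"""Binning, interval filters, signal aggregation and peak statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tfrewire as tw
from oracles import aggregate_by_bases, bins_overlapping, jaccard_by_bases


def iset(records, label="peaks"):
    return tw.IntervalSet.from_records(records, label)


class TestMakeBins:
    @pytest.mark.parametrize(
        "sizes,width,expected",
        [
            ({"chrT": 250}, 100, [("chrT", 0, 100), ("chrT", 100, 200), ("chrT", 200, 250)]),
            ({"chrT": 100}, 100, [("chrT", 0, 100)]),
            ({"chrT": 99}, 100, [("chrT", 0, 99)]),
        ],
    )
    def test_tiling_with_truncation(self, sizes, width, expected):
        grid = tw.make_bins(sizes, width)
        got = list(zip(grid.chroms, grid.starts, grid.ends))
        assert got == expected

    def test_multi_chromosome_count(self):
        grid = tw.make_bins({"c1": 1000, "c2": 300}, 100)
        assert len(grid) == 13  # 10 + 3

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            tw.make_bins({}, 100)
        with pytest.raises(ValueError):
            tw.make_bins({"c": 100}, 0)


class TestFilters:
    def test_empty_blacklist_is_identity(self):
        grid = tw.make_bins({"chrT": 250}, 100)
        assert tw.filter_blacklist(grid, iset([], "blacklist")) == grid

    def test_single_bp_overlap_removes_bin(self):
        grid = tw.make_bins({"chrT": 250}, 100)
        out = tw.filter_blacklist(grid, iset([("chrT", 150, 151)], "blacklist"))
        assert list(zip(out.starts, out.ends)) == [(0, 100), (200, 250)]

    def test_blacklist_matches_per_base_scan(self, rng):
        grid = tw.make_bins({"cA": 30_000, "cB": 20_000}, 100)
        starts = rng.integers(0, 29_000, size=20)
        bl = iset(
            [("cA" if i % 2 else "cB", int(s), int(s + rng.integers(1, 500)))
             for i, s in enumerate(starts)],
            "blacklist",
        )
        out = tw.filter_blacklist(grid, bl)
        removed = set(bins_overlapping(grid, bl))
        assert len(out) == len(grid) - len(removed)
        expected = [i for i in range(len(grid)) if i not in removed]
        assert np.array_equal(out.starts, grid.starts[expected])

    def test_whole_chromosome_peak_keeps_everything(self):
        grid = tw.make_bins({"chrT": 250}, 100)
        assert tw.filter_by_peaks(grid, [iset([("chrT", 0, 250)])]) == grid

    def test_empty_peaks_empty_grid_with_warning(self):
        grid = tw.make_bins({"chrT": 250}, 100)
        with pytest.warns(UserWarning):
            out = tw.filter_by_peaks(grid, [iset([])])
        assert len(out) == 0

    def test_peak_filter_matches_per_base_scan(self, rng):
        grid = tw.make_bins({"cA": 25_000}, 100)
        peaks = [
            iset([("cA", int(s), int(s) + int(w))])
            for s, w in zip(rng.integers(0, 24_000, 8), rng.integers(1, 800, 8))
        ]
        out = tw.filter_by_peaks(grid, peaks)
        pooled = iset(
            [(c, s, e) for p in peaks for c, s, e in zip(p.chroms, p.starts, p.ends)]
        )
        assert len(out) == len(bins_overlapping(grid, pooled))

    def test_filter_composition_shrinks(self, rng):
        grid = tw.make_bins({"cA": 10_000}, 100)
        bl = iset([("cA", 0, 900)], "blacklist")
        pk = [iset([("cA", 500, 4_000)])]
        g1 = tw.filter_blacklist(grid, bl)
        g2 = tw.filter_by_peaks(g1, pk)
        assert len(g2) <= len(g1) <= len(grid)


class TestAggregateSignal:
    def track(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])

    def test_constant_track(self):
        grid = tw.make_bins({"chrT": 250}, 100)
        v = tw.aggregate_signal(grid, self.track([("chrT", 0, 250, 2.0)]))
        assert np.allclose(v, 2.0)

    def test_half_covered_bin_weighted_mean(self):
        grid = tw.make_bins({"chrT": 100}, 100)
        v = tw.aggregate_signal(grid, self.track([("chrT", 0, 50, 4.0)]))
        assert v[0] == pytest.approx(2.0)

    def test_piecewise_track_matches_per_base_oracle(self, rng):
        grid = tw.make_bins({"cA": 2_000, "cB": 500}, 100)
        rows, pos = [], 0
        while pos < 1_900:
            width = int(rng.integers(10, 250))
            if rng.random() < 0.7:
                rows.append(("cA", pos, min(pos + width, 2_000), float(rng.normal(2, 1))))
            pos += width + int(rng.integers(0, 60))
        rows.append(("cB", 30, 470, 1.5))
        track = self.track(rows)
        assert np.allclose(
            tw.aggregate_signal(grid, track), aggregate_by_bases(grid, track)
        )

    def test_overlapping_intervals_rejected(self):
        grid = tw.make_bins({"chrT": 200}, 100)
        with pytest.raises(ValueError, match="overlap"):
            tw.aggregate_signal(
                grid, self.track([("chrT", 0, 60, 1.0), ("chrT", 50, 120, 2.0)])
            )


class TestAverageReplicates:
    def test_mean_behaviour(self):
        v = np.array([0.0, 4.0])
        assert np.array_equal(tw.average_replicates([v]), v)
        assert np.array_equal(tw.average_replicates([v, v]), v)
        assert np.array_equal(
            tw.average_replicates([np.array([0.0, 2.0]), np.array([4.0, 2.0])]),
            np.array([2.0, 2.0]),
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            tw.average_replicates([np.zeros(2), np.zeros(3)])
        with pytest.raises(ValueError):
            tw.average_replicates([])


class TestBuildMatrix:
    def test_hand_computed_fixture(self):
        grid = tw.make_bins({"chrT": 250}, 100)
        t1 = pd.DataFrame(
            [("chrT", 0, 100, 1.0), ("chrT", 100, 250, 3.0)],
            columns=["chrom", "start", "end", "value"],
        )
        t2 = pd.DataFrame(
            [("chrT", 50, 150, 2.0)], columns=["chrom", "start", "end", "value"]
        )
        sm = tw.build_matrix(grid, {"A": [t1], "B": [t2, t2]}, condition=1)
        expected = np.array([[1.0, 1.0], [3.0, 1.0], [3.0, 0.0]])
        assert np.allclose(sm.X, expected)
        assert sm.factors == ["A", "B"]
        assert sm.condition == 1

    def test_constant_tracks_give_constant_columns(self):
        grid = tw.make_bins({"chrT": 400}, 100)
        t = pd.DataFrame(
            [("chrT", 0, 400, 5.0)], columns=["chrom", "start", "end", "value"]
        )
        sm = tw.build_matrix(grid, {"A": [t]})
        assert np.allclose(sm.X, 5.0)

    def test_tsv_round_trip(self, tmp_path):
        grid = tw.make_bins({"chrT": 300}, 100)
        sm = tw.SignalMatrix(
            np.arange(6, dtype=float).reshape(3, 2) / 7, grid, ["A", "B"], 0
        )
        path = tmp_path / "m.tsv"
        sm.to_tsv(path)
        back = tw.SignalMatrix.from_tsv(path)
        assert np.array_equal(back.X, sm.X)
        assert back.factors == sm.factors


class TestPeakStatistics:
    def test_jaccard_examples(self):
        a = iset([("c", 0, 100)])
        assert tw.jaccard_statistic(a, iset([("c", 0, 100)])) == 1.0
        assert tw.jaccard_statistic(a, iset([("c", 200, 300)])) == 0.0
        assert tw.jaccard_statistic(a, iset([("c", 50, 150)])) == pytest.approx(1 / 3)

    def test_jaccard_undefined_for_empty_sets(self):
        with pytest.raises(ValueError):
            tw.jaccard_statistic(iset([]), iset([]))

    @given(st.data())
    def test_jaccard_symmetric_bounded_and_matches_base_scan(self, data):
        def random_set(label):
            n = data.draw(st.integers(1, 5), label=label)
            recs = []
            for _ in range(n):
                s = data.draw(st.integers(0, 500))
                w = data.draw(st.integers(1, 200))
                recs.append(("c", s, s + w))
            return iset(recs)

        a, b = random_set("a"), random_set("b")
        j = tw.jaccard_statistic(a, b)
        assert j == tw.jaccard_statistic(b, a)
        assert 0.0 <= j <= 1.0
        assert j == pytest.approx(jaccard_by_bases(a, b))

    def test_tss_fraction_extremes(self):
        peaks = iset([("c", 0, 100), ("c", 300, 350)])
        tss_on = iset([("c", 10, 11), ("c", 320, 321)], "TSS-anchors")
        assert tw.tss_proximal_fraction(peaks, tss_on, 5000) == 1.0
        tss_far = iset([("c", 100_000, 100_001)], "TSS-anchors")
        assert tw.tss_proximal_fraction(peaks, tss_far, 5000) == 0.0

    def test_tss_fraction_hand_placed_fixture(self):
        # 10 peaks, exactly 4 within 5 kb of an anchor at base 50_000
        tss = iset([("c", 50_000, 50_001)], "TSS-anchors")
        close = [(44_999, 45_100), (48_000, 48_200), (50_000, 50_100), (55_000, 55_050)]
        far = [(i * 100_000 + 200_000, i * 100_000 + 200_100) for i in range(6)]
        peaks = iset([("c", s, e) for s, e in close + far])
        assert tw.tss_proximal_fraction(peaks, tss, 5000) == pytest.approx(0.4)

    def test_tss_boundary_distance(self):
        # peak end at 100 -> last base 99; anchor at 5099 is exactly 5000 away
        peaks = iset([("c", 0, 100)])
        assert tw.tss_proximal_fraction(peaks, iset([("c", 5099, 5100)]), 5000) == 1.0
        assert tw.tss_proximal_fraction(peaks, iset([("c", 5100, 5101)]), 5000) == 0.0

    def test_tss_undefined_without_peaks(self):
        with pytest.raises(ValueError):
            tw.tss_proximal_fraction(iset([]), iset([("c", 0, 1)]), 5000)
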