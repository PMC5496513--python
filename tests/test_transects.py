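import math

import numpy as np
import pandas as pd
import pytest

from kelpscape import io as kio, transects
from kelpscape.errors import CapacityError, SiteTooSmallError


def collinear_track(spacings, covers=None, max_gap=10.0):
    x = np.concatenate([[0.0], np.cumsum(spacings)])
    n = len(x)
    df = pd.DataFrame(
        {
            "site_id": "A",
            "track_order": np.arange(n),
            "x": x,
            "y": np.zeros(n),
            "k": np.zeros(n, dtype=int) if covers is None else (np.asarray(covers) * 25).astype(int),
            "m": 25,
        }
    )
    return kio.build_track(df, max_gap=max_gap)


class TestCandidateStarts:
    def test_single_100m_segment(self):
        track = collinear_track([2.0] * 50)  # 0..100 m
        assert transects.enumerate_candidate_starts(track, 50.0) == [(0.0, 50.0)]

    def test_segment_shorter_than_transect_errors(self):
        track = collinear_track([2.0] * 24, max_gap=10.0)  # 48 m
        with pytest.raises(SiteTooSmallError):
            transects.enumerate_candidate_starts(track, 50.0)

    def test_two_segments_with_gap(self):
        # 60 m segment, 25 m gap, 70 m segment: starts in [0,10] u [85,105]
        spacings = [2.0] * 30 + [25.0] + [2.0] * 35
        track = collinear_track(spacings)
        starts = transects.enumerate_candidate_starts(track, 50.0)
        assert starts == [(0.0, 10.0), (85.0, 105.0)]


class TestDrawDesign:
    def test_single_section_quadrat_count_at_even_spacing(self):
        # aligned 50 m window over 3.8 m spacing holds floor(50/3.8)+1 = 14
        track = collinear_track([3.8] * 40)
        sec = transects._section_at(track, 0.0, 50.0)
        assert sec.n_quadrats == math.floor(50 / 3.8) + 1

    def test_draw_is_reproducible(self):
        track = collinear_track([2.0] * 60)
        a = transects.draw_design(track, 2, seed=9)
        b = transects.draw_design(track, 2, seed=9)
        assert [s.start_dist for s in a] == [s.start_dist for s in b]

    def test_sections_never_overlap(self):
        track = collinear_track([2.0] * 50)  # 100 m
        for seed in range(200):
            secs = transects.draw_design(track, 2, seed=seed)
            (a, b) = sorted(s.start_dist for s in secs)
            assert b >= a + 50.0

    def test_capacity_error_reports_max_feasible(self):
        track = collinear_track([2.0] * 50)  # 100 m: max 2 sections
        with pytest.raises(CapacityError) as err:
            transects.draw_design(track, 3, seed=0)
        assert err.value.max_feasible == 2

    def test_sections_do_not_span_gap_breaks(self):
        spacings = [2.0] * 30 + [25.0] + [2.0] * 35
        track = collinear_track(spacings)
        for seed in range(50):
            for sec in transects.draw_design(track, 2, seed=seed):
                d = track.cum_dist[sec.indices]
                assert np.all(np.diff(d) <= track.max_gap)


class TestTStatistic:
    def test_zero_when_sample_mean_equals_truth(self):
        assert transects.t_statistic([0.2, 0.4], 0.3) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # xbar=0.25, s=0.1291, se=0.06455 -> t = 0.15/0.06455 = 2.324
        t = transects.t_statistic([0.1, 0.2, 0.3, 0.4], 0.1)
        assert t == pytest.approx(2.324, abs=1e-3)

    def test_constant_sample_off_truth_is_infinite(self):
        assert math.isinf(transects.t_statistic([0.5, 0.5, 0.5], 0.2))

    def test_whole_site_as_sample_gives_zero(self):
        rng = np.random.default_rng(3)
        covers = rng.random(100)
        assert transects.t_statistic(covers, covers.mean()) == 0.0


class TestDesignSweep:
    @pytest.fixture(scope="class")
    def patchy_track(self):
        from conftest import make_site_track

        _, _, records = make_site_track(seed=0, n=400)
        return kio.build_track(records)

    def test_row_cardinality(self, patchy_track):
        res = transects.run_design_sweep(patchy_track, n_range=range(1, 6), repeats=5, seed=1)
        assert len(res) <= 25
        assert set(res["n_transects"]) <= set(range(1, 6))

    def test_same_master_seed_identical_tables(self, patchy_track):
        a = transects.run_design_sweep(patchy_track, n_range=[1, 3], repeats=3, seed=4)
        b = transects.run_design_sweep(patchy_track, n_range=[1, 3], repeats=3, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_n_range_rejected(self, patchy_track):
        with pytest.raises(ValueError):
            transects.run_design_sweep(patchy_track, n_range=[], seed=1)

    def test_unbiasedness_of_design_means(self, patchy_track):
        res = transects.run_design_sweep(patchy_track, n_range=[3], repeats=500, seed=2)
        bias = res["mean_cover"].mean() - patchy_track.covers.mean()
        assert abs(bias) < 0.01

    def test_no_reuse_mode_is_disjoint_across_repeats(self, patchy_track):
        res = transects.run_design_sweep(
            patchy_track, n_range=[2], repeats=3, seed=5, no_reuse_across_repeats=True
        )
        # 3 repeats x 2 sections of disjoint quadrats
        assert res["n_quadrats"].sum() <= patchy_track.n


class TestRequiredTransects:
    @staticmethod
    def _frame(rows):
        return pd.DataFrame(rows, columns=["site_id", "n_transects", "repeat", "t_value"]).assign(
            mean_cover=0.0, se=0.0, n_quadrats=0
        )

    def test_all_zero_t_gives_min_n(self):
        rows = [("A", n, r, 0.0) for n in (1, 2, 3) for r in range(5)]
        assert transects.required_transects(self._frame(rows)) == 1

    def test_threshold_crossing_scan(self):
        # t < 2 only from n=12 onward in all repeats
        rows = []
        for n in range(10, 15):
            for r in range(5):
                rows.append(("A", n, r, 3.0 if n < 12 else 1.0))
        assert transects.required_transects(self._frame(rows)) == 12

    def test_failure_at_largest_n_means_none(self):
        rows = [("A", n, r, 1.0) for n in (1, 2, 3) for r in range(5)]
        rows.append(("A", 3, 5, 3.0))
        assert transects.required_transects(self._frame(rows)) is None
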