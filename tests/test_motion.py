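"""COM geometry, filter chain, sub-area scores, binarization and errors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import butter, sosfreqz

from fibermat import AnnotationTrack, Epoch, SensorGridSpec
from fibermat import motion as mot
from fibermat.core import EmptyGridError, InsufficientDataError, LIMBS, Limb
from fibermat.position import WindowMedianMap


def wmap(medians, k=0):
    return WindowMedianMap(window_index=k, start_s=10.0 * k,
                           medians=np.asarray(medians, dtype=float))


class TestCom:
    def test_point_mass(self):
        m = np.zeros((8, 5))
        m[3, 2] = 11.0
        assert mot.compute_com(wmap(m)) == (4.0, 3.0)

    def test_uniform_pressure_is_grid_center(self):
        assert mot.compute_com(wmap(np.ones((8, 5)))) == (4.5, 3.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_matches_double_loop_oracle(self, seed):
        m = np.random.default_rng(seed).gamma(1.0, 2.0, size=(8, 5))
        row, col = mot.compute_com(wmap(m))
        p_tot = sr = sc = 0.0
        for i in range(8):
            for j in range(5):
                p_tot += m[i, j]
                sr += (i + 1) * m[i, j]
                sc += (j + 1) * m[i, j]
        assert abs(row - sr / p_tot) < 1e-12
        assert abs(col - sc / p_tot) < 1e-12

    def test_row_translation_equivariance(self):
        rng = np.random.default_rng(2)
        m = np.zeros((8, 5))
        m[1:4, 1:4] = rng.gamma(2.0, 1.0, size=(3, 3))
        r0, c0 = mot.compute_com(wmap(m))
        r1, c1 = mot.compute_com(wmap(np.roll(m, 1, axis=0)))
        assert r1 == pytest.approx(r0 + 1, abs=1e-12)
        assert c1 == pytest.approx(c0, abs=1e-12)

    def test_zero_pressure_raises(self):
        with pytest.raises(EmptyGridError):
            mot.compute_com(wmap(np.zeros((8, 5))))

    def test_track_carries_forward_and_warns_on_empty_start(self, grid):
        hot = np.zeros((8, 5))
        hot[4, 2] = 3.0
        maps = [wmap(np.zeros((8, 5)), 0), wmap(hot, 1), wmap(np.zeros((8, 5)), 2)]
        with pytest.warns(UserWarning, match="grid center"):
            track = mot.com_track(maps, grid)
        assert track.snapped[0] == (4, 3)  # center, tie toward center
        assert track.snapped[1] == (5, 3)
        assert track.snapped[2] == (5, 3)  # carried forward


class TestSnap:
    def test_ties_round_toward_grid_center(self, grid):
        assert mot.snap_com((2.5, 3.0), grid) == (3, 3)
        assert mot.snap_com((6.5, 3.0), grid) == (6, 3)
        assert mot.snap_com((4.0, 1.5), grid) == (4, 2)
        assert mot.snap_com((4.0, 4.5), grid) == (4, 4)

    def test_plain_rounding(self, grid):
        assert mot.snap_com((4.2, 2.8), grid) == (4, 3)
        assert mot.snap_com((5.7, 4.3), grid) == (6, 4)


class TestLayout:
    def test_central_com_full_area(self, grid):
        layout = mot.layout_area((4, 3), grid)
        rows = sorted({r for r, _ in layout.area})
        cols = sorted({c for _, c in layout.area})
        assert rows == [1, 2, 3, 4, 5, 6]
        assert cols == [2, 3, 4]
        assert layout.m == 18 and not layout.edge_case
        for limb in LIMBS:
            assert len(layout.subareas[limb]) == 6
            assert set(layout.subareas[limb]) <= set(layout.area)

    def test_subarea_geometry_conventions(self, grid):
        layout = mot.layout_area((4, 3), grid)
        assert set(layout.subareas[Limb.LA]) == {(r, c) for r in (1, 2, 3)
                                                for c in (2, 3)}
        assert set(layout.subareas[Limb.RL]) == {(r, c) for r in (4, 5, 6)
                                                for c in (3, 4)}

    def test_head_high_mirrors_arm_rows(self, grid):
        layout = mot.layout_area((4, 3), grid, head_row_end="high")
        assert set(layout.subareas[Limb.LA]) == {(r, c) for r in (4, 5, 6)
                                                for c in (2, 3)}

    def test_edge_com_clipped_to_five_rows(self, grid):
        layout = mot.layout_area((2, 3), grid)
        rows = sorted({r for r, _ in layout.area})
        assert rows == [1, 2, 3, 4, 5]
        assert layout.m == 15 and layout.edge_case
        for limb in LIMBS:
            assert len(layout.subareas[limb]) == 6

    def test_edge_column_widened(self, grid):
        layout = mot.layout_area((4, 1), grid)
        cols = sorted({c for _, c in layout.area})
        assert cols == [1, 2, 3]
        assert layout.widened

    def test_m_is_always_15_or_18(self, grid):
        for r in range(1, 9):
            for c in range(1, 6):
                assert mot.layout_area((r, c), grid).m in (15, 18)

    def test_narrow_grid_unsupported(self):
        with pytest.raises(Exception):
            mot.layout_area((3, 1), SensorGridSpec(n_rows=8, n_cols=2))


class TestFilterChain:
    def test_dc_input_killed(self):
        out = mot.filter_chain(np.full(6000, 7.3))
        assert np.max(np.abs(out)) < 1e-6
        assert np.max(np.abs(mot.bandpass_stage(np.full(6000, 7.3)))) < 1e-6

    def test_passband_gain_near_unity(self):
        """Analytic response of the designed bandpass at 0.1 Hz (one pass);
        well within 1 dB of unity."""
        sos = butter(4, mot.BAND_HZ, btype="bandpass", fs=50.0, output="sos")
        _, h = sosfreqz(sos, worN=2 * np.pi * np.array([0.1]) / 50.0)
        gain_db = 20 * np.log10(np.abs(h[0]))
        assert abs(gain_db) < 1.0

    def test_stopband_attenuation_at_5hz(self):
        sos = butter(4, mot.BAND_HZ, btype="bandpass", fs=50.0, output="sos")
        _, h = sosfreqz(sos, worN=2 * np.pi * np.array([5.0]) / 50.0)
        assert 20 * np.log10(np.abs(h[0])) < -40.0

    def test_linear_stage_scales_with_amplitude(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=5000)
        assert np.allclose(
            mot.bandpass_stage(2 * x), 2 * mot.bandpass_stage(x), atol=1e-9
        )

    def test_context_cropping_preserves_length(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=600)
        ctx = rng.normal(size=1500)
        out = mot.filter_chain(x, context_before=ctx, context_after=ctx)
        assert out.shape == x.shape

    def test_too_short_segment_rejected(self):
        with pytest.raises(InsufficientDataError):
            mot.filter_chain(np.ones(20))


class TestScores:
    def _layout(self, grid):
        return mot.layout_area((4, 3), grid)

    def test_point_variance_in_unshared_sensor(self, grid):
        layout = self._layout(grid)
        var = np.zeros((8, 5))
        var[4, 1] = 3.0  # (5,2): LL only (column 2 is not shared)
        scores = mot.score_subareas(var, layout)
        assert scores[Limb.LL] == 1.0
        assert scores[Limb.RL] == scores[Limb.LA] == scores[Limb.RA] == 0.0

    def test_shared_column_counted_for_both_sides(self, grid):
        layout = self._layout(grid)
        var = np.zeros((8, 5))
        var[4, 2] = 2.0  # (5,3): middle column, lower half
        scores = mot.score_subareas(var, layout)
        assert scores[Limb.LL] == scores[Limb.RL] == 1.0
        assert scores[Limb.LA] == scores[Limb.RA] == 0.0

    def test_uniform_variance_gives_one_third(self, grid):
        layout = self._layout(grid)
        scores = mot.score_subareas(np.ones((8, 5)), layout)
        for limb in LIMBS:
            assert scores[limb] == pytest.approx(1 / 3, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_matches_direct_summation_oracle(self, seed):
        layout = mot.layout_area((4, 3), SensorGridSpec())
        var = np.random.default_rng(seed).gamma(1.0, 1.0, size=(8, 5))
        scores = mot.score_subareas(var, layout)
        total = sum(var[r - 1, c - 1] for r, c in layout.area)
        for limb in LIMBS:
            expect = sum(var[r - 1, c - 1] for r, c in layout.subareas[limb]) / total
            assert abs(scores[limb] - expect) < 1e-12

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_score_sum_between_one_and_two(self, seed):
        """Non-edge layouts: the four limb blocks cover the area once plus the
        shared middle column, so the score sum is 1 + mid/total in [1, 2]."""
        layout = mot.layout_area((5, 3), SensorGridSpec())
        var = np.random.default_rng(seed).gamma(1.0, 1.0, size=(8, 5))
        scores = mot.score_subareas(var, layout)
        total = sum(scores.values())
        assert 1.0 - 1e-12 <= total <= 2.0 + 1e-12
        mid = sum(var[r - 1, 2] for r, _ in layout.area if _ == 3)
        area_total = sum(var[r - 1, c - 1] for r, c in layout.area)
        assert total == pytest.approx(1 + mid / area_total, abs=1e-12)

    def test_zero_variance_marks_still(self, grid):
        assert mot.score_subareas(np.zeros((8, 5)), self._layout(grid)) is None


def _series(values_per_limb):
    n = len(next(iter(values_per_limb.values())))
    scores = [
        {limb: values_per_limb[limb][k] for limb in LIMBS} for k in range(n)
    ]
    return mot.SubAreaScoreSeries(scores=scores, start_s=np.arange(n) * 10.0)


class TestBinarize:
    def test_hundred_distinct_scores_flag_exactly_five(self):
        vals = np.arange(1.0, 101.0)
        series = _series({limb: vals for limb in LIMBS})
        track = mot.binarize(series)
        assert track.moving[:, 0].sum() == 5
        assert set(np.nonzero(track.moving[:, 0])[0]) == {95, 96, 97, 98, 99}

    def test_all_equal_scores_flag_nothing(self):
        series = _series({limb: np.ones(50) for limb in LIMBS})
        track = mot.binarize(series)
        assert track.moving.sum() == 0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 500), n=st.integers(20, 200))
    def test_flag_count_bounded_by_five_percent(self, seed, n):
        vals = np.random.default_rng(seed).uniform(size=n)
        series = _series({limb: vals for limb in LIMBS})
        track = mot.binarize(series)
        assert track.moving[:, 0].sum() <= int(np.ceil(0.05 * n))

    def test_few_windows_warns(self):
        series = _series({limb: np.arange(5.0) for limb in LIMBS})
        with pytest.warns(UserWarning, match="percentile"):
            mot.binarize(series)


class TestStillAndErrors:
    def _track(self, moving):
        moving = np.asarray(moving, dtype=bool)
        return mot.BinaryMotionTrack(
            moving=moving,
            thresholds={limb: 0.5 for limb in LIMBS},
            start_s=np.arange(moving.shape[0]) * 10.0,
        )

    def test_still_periods_require_all_limbs_quiet(self):
        track = self._track(
            [[0, 0, 0, 0], [1, 1, 1, 1], [1, 0, 0, 0]]
        )
        assert mot.still_periods(track) == [0]

    def test_identical_device_and_annotation_zero_error(self):
        moving = np.zeros((30, 4), dtype=bool)
        moving[4] = True  # gross epoch: all four limbs
        moving[10, 0] = True  # fine LL epoch
        epochs = [Epoch("still")] * 30
        epochs[4] = Epoch("gross", frozenset({Limb.LL}))
        epochs[10] = Epoch("fine", frozenset({Limb.LL}))
        err = mot.movement_error(self._track(moving), AnnotationTrack(epochs=epochs))
        assert all(v == 0.0 for v in err.values())

    def test_three_vs_six_epochs_is_minus_ten_percent(self):
        moving = np.zeros((30, 4), dtype=bool)
        moving[:3, 0] = True  # device: 3/30 epochs on LL
        epochs = [
            Epoch("fine", frozenset({Limb.LL})) if k < 6 else Epoch("still")
            for k in range(30)
        ]
        err = mot.movement_error(self._track(moving), AnnotationTrack(epochs=epochs))
        assert err["LL"] == pytest.approx(-10.0)

    def test_excluded_epochs_removed_from_both(self):
        moving = np.zeros((30, 4), dtype=bool)
        moving[0, 0] = True
        epochs = [Epoch("still")] * 30
        epochs[0] = Epoch("intervention")  # the lone device detection is discarded
        err = mot.movement_error(self._track(moving), AnnotationTrack(epochs=epochs))
        assert err["LL"] == 0.0

    def test_no_full_block_rejected(self):
        moving = np.zeros((10, 4), dtype=bool)
        with pytest.raises(InsufficientDataError):
            mot.movement_error(
                self._track(moving),
                AnnotationTrack(epochs=[Epoch("still")] * 10),
            )


class TestComDistribution:
    def test_single_cell_histogram(self, grid):
        track = mot.ComTrack(
            rows=np.full(7, 4.0),
            cols=np.full(7, 3.0),
            snapped=[(4, 3)] * 7,
            start_s=np.arange(7) * 10.0,
        )
        dist = mot.com_distribution(track, grid)
        assert dist["counts"][3, 2] == 7
        assert dist["counts"].sum() == 7
        assert dist["edge_rows_empty"] and dist["edge_cols_empty"]
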