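"""Flight statistics: closed-form cases, properties, and video-vs-truth
equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tunnelvision import (
    FlightTrack,
    TrajectorySpec,
    assemble_track,
    clip_to_analysis_region,
    compute_track_metrics,
    cross_index,
    detect_sequence,
    filter_complete_flights,
    height_proxy,
    lateral_movement_proportion,
    median_lateral_position,
    median_speed,
    render_track_video,
    simulate_track,
)


def track_from(x, y, fps=50.0, **kw):
    return FlightTrack.from_arrays(x, y, fps=fps, **kw)


class TestClip:
    def test_grid_track_keeps_81_points(self):
        # points every 10 mm over 0-1000: those in [100, 900] number 81
        x = np.arange(0.0, 1001.0, 10.0)
        clipped = clip_to_analysis_region(track_from(x, np.zeros_like(x)))
        assert len(clipped) == 81

    def test_track_outside_region_raises(self):
        x = np.linspace(0, 90, 10)
        with pytest.raises(ValueError, match="analysis region"):
            clip_to_analysis_region(track_from(x, np.zeros_like(x)))

    def test_inside_track_unchanged(self):
        x = np.linspace(200, 800, 50)
        clipped = clip_to_analysis_region(track_from(x, np.zeros_like(x)))
        assert len(clipped) == 50


class TestMedianLateralPosition:
    def test_midline_flight_zero(self):
        x = np.linspace(100, 900, 30)
        assert median_lateral_position(track_from(x, np.zeros_like(x))) == 0.0

    def test_odd_median(self):
        t = track_from([100, 200, 300], [-50.0, -50.0, 100.0])
        assert median_lateral_position(t) == -50.0

    def test_symmetric_oscillation_about_offset(self):
        x = np.linspace(100, 900, 200)
        y = 30.0 + 20.0 * np.sin(2 * np.pi * x / 200.0)
        assert median_lateral_position(track_from(x, y)) == pytest.approx(30.0, abs=0.5)


class TestMedianSpeed:
    def test_constant_step_5mm_at_50fps_gives_250(self):
        x = np.arange(0.0, 500.0, 5.0)
        assert median_speed(track_from(x, np.zeros_like(x))) == pytest.approx(250.0)

    def test_stationary_track_zero(self):
        t = track_from([300.0] * 10, [0.0] * 10)
        assert median_speed(t) == 0.0

    def test_alternating_steps_midpoint_median(self):
        # steps alternate 3 and 4 mm/frame: median of {150, 200} = 175 mm/s
        steps = np.tile([3.0, 4.0], 10)
        x = np.concatenate([[0.0], np.cumsum(steps)])
        assert median_speed(track_from(x, np.zeros_like(x))) == pytest.approx(175.0)

    def test_single_record_rejected(self):
        with pytest.raises(ValueError):
            t = track_from([1.0, 2.0], [0.0, 0.0])
            t.data = t.data.iloc[:1]
            median_speed(t)


class TestLateralMovementProportion:
    def test_pure_longitudinal_zero(self):
        x = np.arange(0.0, 100.0, 2.0)
        assert lateral_movement_proportion(track_from(x, np.zeros_like(x))) == 0.0

    @pytest.mark.parametrize(
        "dx,dy,expected", [(3.0, 4.0, 4.0 / 3.0), (2.0, 2.0, 1.0)]
    )
    def test_constant_step_ratio(self, dx, dy, expected):
        n = 30
        x = np.arange(n) * dx
        y = np.arange(n) * dy
        assert lateral_movement_proportion(track_from(x, y)) == pytest.approx(expected)

    def test_hovering_track_rejected(self):
        t = track_from([5.0] * 10, [2.0] * 10)
        with pytest.raises(ValueError, match="degenerate"):
            lateral_movement_proportion(t)

    def test_purely_lateral_steps_capped(self):
        t = track_from([500.0] * 10, np.arange(10.0) * 5.0)
        assert lateral_movement_proportion(t) == 100.0


class TestCrossIndex:
    def test_straight_track_zero(self):
        x = np.linspace(100, 900, 100)
        assert cross_index(track_from(x, np.full_like(x, 42.0))) == 0.0

    def test_window_means_subtract(self):
        x = np.linspace(100, 900, 400)
        y = np.where(x < 500, 50.0, -70.0)
        assert cross_index(track_from(x, y)) == pytest.approx(-120.0)

    def test_linear_track_derived_value(self):
        # oracle: medians of a linear function over symmetric windows are its
        # midpoint values, so the index is 0.2 * (700 - 300) = +80 mm
        x = np.linspace(0, 1000, 2001)
        y = -100.0 + 0.2 * x
        expected = (-100.0 + 0.2 * 700.0) - (-100.0 + 0.2 * 300.0)
        assert expected == pytest.approx(80.0)
        assert cross_index(track_from(x, y)) == pytest.approx(expected, abs=1e-6)

    def test_empty_window_rejected(self):
        x = np.linspace(100, 500, 50)  # never reaches the exit window
        with pytest.raises(ValueError, match="cross-index undefined"):
            cross_index(track_from(x, np.zeros_like(x)))

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_antisymmetric_under_mirroring(self, seed):
        rng = np.random.default_rng(seed)
        x = np.linspace(100, 900, 120)
        y = rng.normal(0.0, 40.0, len(x)).cumsum() / 10.0
        y = np.clip(y, -150, 150)
        a = cross_index(track_from(x, y))
        b = cross_index(track_from(x, -y))
        assert a == pytest.approx(-b, abs=1e-9)
        # speed is invariant under the same mirroring
        assert median_speed(track_from(x, y)) == pytest.approx(
            median_speed(track_from(x, -y))
        )


class TestHeightProxy:
    def test_constant_area_returned(self):
        t = track_from(np.linspace(100, 900, 20), np.zeros(20), area_px2=np.full(20, 300.0))
        assert height_proxy(t) == 300.0

    def test_interpolated_only_rejected(self):
        t = track_from(
            np.linspace(100, 900, 20),
            np.zeros(20),
            interpolated=np.ones(20, bool),
        )
        with pytest.raises(ValueError, match="interpolated"):
            height_proxy(t)

    def test_low_flight_has_larger_proxy_than_high(self, camera, calibration):
        proxies = []
        for z in (60.0, 240.0):
            sim = simulate_track(
                TrajectorySpec(height_mm=z, speed_mm_s=1200.0, seed=4)
            )
            video = render_track_video(sim, camera, seed=4)
            track = assemble_track(detect_sequence(video), calibration, fps=video.fps)
            proxies.append(height_proxy(clip_to_analysis_region(track)))
        assert proxies[0] > proxies[1]


class TestPipelineEquivalence:
    def test_metrics_from_video_match_ground_truth(self, camera, calibration):
        # metrics computed on the tracked rendered video agree with metrics
        # computed directly on the simulated ground truth
        spec = TrajectorySpec(
            regime="diagonal_cross",
            entry_offset_mm=-80.0,
            exit_offset_mm=80.0,
            seed=21,
        )
        sim = simulate_track(spec)
        truth = compute_track_metrics(FlightTrack.from_ground_truth(sim))
        video = render_track_video(sim, camera, seed=21)
        track = assemble_track(detect_sequence(video), calibration, fps=video.fps)
        (accepted,) = filter_complete_flights([track])
        measured = compute_track_metrics(accepted)
        assert measured.median_lateral_position_mm == pytest.approx(
            truth.median_lateral_position_mm, abs=2.0
        )
        assert measured.median_speed_mm_s == pytest.approx(
            truth.median_speed_mm_s, rel=0.05
        )
        assert measured.lateral_movement_proportion == pytest.approx(
            truth.lateral_movement_proportion, abs=0.05
        )
        assert measured.cross_index_mm == pytest.approx(truth.cross_index_mm, abs=5.0)
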