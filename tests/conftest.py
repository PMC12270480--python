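import pytest

from tunnelvision import (
    Calibration,
    SceneSpec,
    TexturedPlane,
    TrajectorySpec,
    TunnelCamera,
    assemble_track,
    detect_sequence,
    render_track_video,
    simulate_track,
)


@pytest.fixture(scope="session")
def camera():
    return TunnelCamera()


@pytest.fixture(scope="session")
def calibration(camera):
    return Calibration(
        px_per_mm_x=camera.px_per_mm,
        px_per_mm_y=camera.px_per_mm,
        origin_col=camera.origin_col,
        midline_row=(camera.image_size[1] - 1) / 2.0,
    )


@pytest.fixture(scope="session")
def straight_flight(camera, calibration):
    """Noiseless off-centre straight flight: ground truth, video, tracked track."""
    spec = TrajectorySpec(regime="offset_straight", entry_offset_mm=40.0, seed=11)
    sim = simulate_track(spec)
    video = render_track_video(sim, camera, seed=11)
    track = assemble_track(detect_sequence(video), calibration, fps=video.fps)
    return sim, video, track


@pytest.fixture(scope="session")
def floor_scene():
    """Fast forward translation over a noise-textured ground plane."""
    return SceneSpec(
        planes=(TexturedPlane(800.0, "floor", "noise", 0.9, 400.0),),
        camera_speed=600.0,
        fps=30.0,
        duration=0.2,
        image_size=(120, 120),
        seed=5,
    )
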