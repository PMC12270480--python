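"""Flight statistics computed from a calibrated tunnel track.

All metrics are evaluated on the central 80 cm of the tunnel
(x in [100, 900] mm) to exclude frames where the flight cages are
visible.  Medians use the midpoint convention for even counts.

The four per-flight statistics:

- median lateral position: median signed offset from the tunnel midline;
- median speed: median frame-to-frame 2-D (x, y) speed — the bottom-mounted
  camera does not see height, so z never enters;
- lateral movement proportion: median per-frame ratio |dy| / |dx|;
- cross-index: lateral position in the pre-exit window (600-800 mm) minus
  the post-entry window (200-400 mm) — positive means the flight drifted
  towards +y while traversing.

The height proxy is the median silhouette area (larger = lower flight).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracking import FlightTrack

__all__ = [
    "TrackMetrics",
    "clip_to_analysis_region",
    "median_lateral_position",
    "median_speed",
    "lateral_movement_proportion",
    "cross_index",
    "height_proxy",
    "compute_track_metrics",
]

ANALYSIS_X_MM = (100.0, 900.0)
ENTRY_WINDOW_MM = (200.0, 400.0)
EXIT_WINDOW_MM = (600.0, 800.0)
#: Displacements below this are treated as stationary on that axis.
DEGENERATE_STEP_MM = 0.1
#: Capped ratio for purely lateral steps (|dx| ~ 0 but the moth moved sideways).
LATERAL_RATIO_CAP = 100.0


@dataclass(frozen=True)
class TrackMetrics:
    """The four flight statistics plus height proxy for one track."""

    median_lateral_position_mm: float
    median_speed_mm_s: float
    lateral_movement_proportion: float
    cross_index_mm: float
    height_proxy_px2: float
    n_frames: int
    condition_id: str = ""

    def as_dict(self) -> dict:
        return {
            "condition_id": self.condition_id,
            "median_lateral_position_mm": self.median_lateral_position_mm,
            "median_speed_mm_s": self.median_speed_mm_s,
            "lateral_movement_proportion": self.lateral_movement_proportion,
            "cross_index_mm": self.cross_index_mm,
            "height_proxy_px2": self.height_proxy_px2,
            "n_frames": self.n_frames,
        }


def clip_to_analysis_region(
    track: FlightTrack, x_range_mm: tuple[float, float] = ANALYSIS_X_MM
) -> FlightTrack:
    """Restrict a track to the central analysis region of the tunnel."""
    lo, hi = x_range_mm
    df = track.data[(track.data["x_mm"] >= lo) & (track.data["x_mm"] <= hi)]
    if len(df) < 2:
        raise ValueError("track outside analysis region")
    return FlightTrack(
        data=df.reset_index(drop=True),
        fps=track.fps,
        calibration=track.calibration,
        condition_id=track.condition_id,
    )


def median_lateral_position(track: FlightTrack) -> float:
    """Median signed lateral offset from the midline, mm."""
    return float(np.median(track.data["y_mm"].to_numpy()))


def median_speed(track: FlightTrack) -> float:
    """Median frame-to-frame speed, mm/s (2-D, interpolated frames included)."""
    if len(track) < 2:
        raise ValueError("speed needs >= 2 records")
    dx = np.diff(track.data["x_mm"].to_numpy())
    dy = np.diff(track.data["y_mm"].to_numpy())
    dt = np.diff(track.data["frame"].to_numpy()) / track.fps
    return float(np.median(np.hypot(dx, dy) / dt))


def lateral_movement_proportion(track: FlightTrack) -> float:
    """Median per-frame ratio of lateral to longitudinal displacement.

    Frames where both |dx| and |dy| fall below 0.1 mm are hovering and are
    skipped; frames with negligible |dx| but real lateral motion contribute
    a capped ratio of 100 so the median stays finite yet monotone in
    lateral activity.
    """
    if len(track) < 2:
        raise ValueError("proportion needs >= 2 records")
    dx = np.abs(np.diff(track.data["x_mm"].to_numpy()))
    dy = np.abs(np.diff(track.data["y_mm"].to_numpy()))
    hovering = (dx < DEGENERATE_STEP_MM) & (dy < DEGENERATE_STEP_MM)
    dx, dy = dx[~hovering], dy[~hovering]
    if len(dx) == 0:
        raise ValueError("all steps degenerate (hovering track)")
    with np.errstate(divide="ignore"):
        ratio = np.where(dx < DEGENERATE_STEP_MM, LATERAL_RATIO_CAP, dy / np.maximum(dx, 1e-12))
    ratio = np.minimum(ratio, LATERAL_RATIO_CAP)
    return float(np.median(ratio))


def cross_index(
    track: FlightTrack,
    entry_window_mm: tuple[float, float] = ENTRY_WINDOW_MM,
    exit_window_mm: tuple[float, float] = EXIT_WINDOW_MM,
    statistic: str = "median",
) -> float:
    """Lateral position change between the entry and exit thirds, mm.

    ``stat(y | x in exit window) - stat(y | x in entry window)`` with the
    window statistic defaulting to the median (``statistic="mean"``
    switches to the mean).
    """
    stat = {"median": np.median, "mean": np.mean}[statistic]
    x = track.data["x_mm"].to_numpy()
    y = track.data["y_mm"].to_numpy()
    in_entry = (x >= entry_window_mm[0]) & (x <= entry_window_mm[1])
    in_exit = (x >= exit_window_mm[0]) & (x <= exit_window_mm[1])
    if not in_entry.any() or not in_exit.any():
        raise ValueError("cross-index undefined: empty window")
    return float(stat(y[in_exit]) - stat(y[in_entry]))


def height_proxy(track: FlightTrack) -> float:
    """Median silhouette area over non-interpolated records, px^2.

    Larger area means the moth flew closer to the bottom-mounted camera,
    i.e. lower in the tunnel.
    """
    real = track.data[~track.data["interpolated"].astype(bool)]
    if len(real) == 0:
        raise ValueError("height proxy undefined: only interpolated records")
    return float(np.median(real["area_px2"].to_numpy()))


def compute_track_metrics(track: FlightTrack, clip: bool = True) -> TrackMetrics:
    """All per-flight statistics for one calibrated track."""
    clipped = clip_to_analysis_region(track) if clip else track
    return TrackMetrics(
        median_lateral_position_mm=median_lateral_position(clipped),
        median_speed_mm_s=median_speed(clipped),
        lateral_movement_proportion=lateral_movement_proportion(clipped),
        cross_index_mm=cross_index(clipped),
        height_proxy_px2=height_proxy(clipped),
        n_frames=len(clipped),
        condition_id=track.condition_id,
    )
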