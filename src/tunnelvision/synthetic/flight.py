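"""Simulated moth trajectories and top-down silhouette videos.

The flight tunnel is 100 x 30 x 30 cm; a camera 1.5 m below films it at
50 fps, 640 x 480 px.  The moth appears as a dark-adapted bright blob whose
apparent area shrinks with height above the floor (the camera is below, so
larger area = lower flight) — the same area-as-height proxy the tracking
layer exploits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..frames import FrameSequence
from ..specs import (
    TUNNEL_HALF_WIDTH_MM,
    TUNNEL_HEIGHT_MM,
    TUNNEL_LENGTH_MM,
    TrajectorySpec,
    spec_hash,
)

__all__ = [
    "SimulatedTrack",
    "TunnelCamera",
    "simulate_track",
    "render_track_video",
    "compute_viewing_angle",
]


def compute_viewing_angle(feature_size_mm: float, distance_mm: float) -> float:
    """Angle (degrees) subtended by a feature of the given size at a distance.

    ``2 * atan(size / (2 * distance))`` — e.g. the tunnel's 13.9 mm wall
    checkers subtend 5.3 degrees from the tunnel centre (150 mm away).
    """
    if distance_mm <= 0:
        raise ValueError("distance must be > 0")
    if feature_size_mm < 0:
        raise ValueError("feature size must be >= 0")
    return math.degrees(2.0 * math.atan(feature_size_mm / (2.0 * distance_mm)))


@dataclass
class SimulatedTrack:
    """Ground-truth tunnel trajectory: frame, x_mm, y_mm, z_mm at ``fps``."""

    data: pd.DataFrame
    fps: float
    spec: TrajectorySpec | None = None

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _lateral_profile(spec: TrajectorySpec, x: np.ndarray) -> np.ndarray:
    third = TUNNEL_LENGTH_MM / 3.0
    if spec.regime == "straight_centred":
        return np.zeros_like(x)
    if spec.regime == "offset_straight":
        return np.full_like(x, spec.entry_offset_mm)
    if spec.regime == "diagonal_cross":
        # hold entry offset, cross linearly over the central third, hold exit
        frac = np.clip((x - third) / third, 0.0, 1.0)
        return spec.entry_offset_mm + frac * (spec.exit_offset_mm - spec.entry_offset_mm)
    if spec.regime == "oscillating":
        return spec.oscillation_amplitude_mm * np.sin(
            2 * np.pi * x / spec.oscillation_period_mm
        )
    # piecewise: single linear ramp over the whole tunnel
    frac = x / TUNNEL_LENGTH_MM
    return spec.entry_offset_mm + frac * (spec.exit_offset_mm - spec.entry_offset_mm)


def simulate_track(spec: TrajectorySpec) -> SimulatedTrack:
    """Generate a ground-truth traversal of the tunnel at 0-1000 mm.

    The longitudinal coordinate runs exactly from 0 to 1000 mm at the
    spec's nominal speed; lateral and height profiles follow the regime,
    with optional seeded Gaussian positional noise on y and z.
    """
    step = spec.speed_mm_s / spec.fps
    n = int(round(TUNNEL_LENGTH_MM / step)) + 1
    if n < 2:
        raise ValueError("speed too high for even two frames in the tunnel")
    x = np.linspace(0.0, TUNNEL_LENGTH_MM, n)
    y = _lateral_profile(spec, x)
    if spec.height_profile == "ramp":
        z = spec.height_mm + spec.height_amplitude_mm * (2 * x / TUNNEL_LENGTH_MM - 1)
    else:
        z = spec.height_mm + spec.height_amplitude_mm * np.sin(
            2 * np.pi * x / TUNNEL_LENGTH_MM
        )
    if spec.noise_sd_mm > 0:
        rng = np.random.default_rng(spec.seed)
        y = y + rng.normal(0.0, spec.noise_sd_mm, n)
        z = z + rng.normal(0.0, spec.noise_sd_mm, n)
    y = np.clip(y, -TUNNEL_HALF_WIDTH_MM, TUNNEL_HALF_WIDTH_MM)
    z = np.clip(z, 5.0, TUNNEL_HEIGHT_MM - 5.0)
    data = pd.DataFrame(
        {"frame": np.arange(n), "x_mm": x, "y_mm": y, "z_mm": z}
    )
    return SimulatedTrack(data=data, fps=spec.fps, spec=spec)


@dataclass(frozen=True)
class TunnelCamera:
    """Bottom-mounted tunnel camera: linear px/mm mapping plus a depth-scaled
    blob size.

    The centroid mapping is a fixed per-axis calibration (no parallax); only
    the silhouette *size* carries the perspective cue, shrinking as
    ``depth / (depth + z)`` for a moth at height ``z`` above the floor.
    """

    image_size: tuple[int, int] = (640, 480)
    px_per_mm: float = 0.6
    origin_col: float = 20.0  # pixel column of tunnel entrance (x = 0)
    camera_depth_mm: float = 1500.0  # camera distance below the tunnel floor
    blob_radius_floor_px: float = 9.0
    background: float = 0.15
    foreground: float = 0.85

    def to_px(self, x_mm: np.ndarray, y_mm: np.ndarray):
        col = self.origin_col + np.asarray(x_mm) * self.px_per_mm
        row = (self.image_size[1] - 1) / 2.0 - np.asarray(y_mm) * self.px_per_mm
        return col, row

    def to_mm(self, col: np.ndarray, row: np.ndarray):
        x = (np.asarray(col) - self.origin_col) / self.px_per_mm
        y = ((self.image_size[1] - 1) / 2.0 - np.asarray(row)) / self.px_per_mm
        return x, y

    def blob_radius(self, z_mm: float) -> float:
        return self.blob_radius_floor_px * self.camera_depth_mm / (
            self.camera_depth_mm + z_mm
        )


def render_track_video(
    track: SimulatedTrack,
    camera: TunnelCamera | None = None,
    pixel_noise_sd: float = 0.0,
    seed: int = 0,
) -> FrameSequence:
    """Render a silhouette video of a simulated flight.

    One video frame per track record; the moth is an anti-aliased filled
    disc whose radius follows ``camera.blob_radius`` so apparent area
    strictly decreases with height.
    """
    if camera is None:
        camera = TunnelCamera()
    if len(track) < 2:
        raise ValueError("empty video: track must have >= 2 records")
    w, h = camera.image_size
    xs = track.data["x_mm"].to_numpy()
    ys = track.data["y_mm"].to_numpy()
    zs = track.data["z_mm"].to_numpy()
    if xs.min() < -1e-6 or xs.max() > TUNNEL_LENGTH_MM + 1e-6:
        raise ValueError("track outside tunnel bounds")
    cols, rows = camera.to_px(xs, ys)
    rng = np.random.default_rng(seed)

    frames = np.full((len(track), h, w), camera.background)
    for i, (cc, cr, z) in enumerate(zip(cols, rows, zs)):
        r = camera.blob_radius(z)
        pad = int(np.ceil(r)) + 2
        c0, c1 = int(np.floor(cc)) - pad, int(np.floor(cc)) + pad + 1
        r0, r1 = int(np.floor(cr)) - pad, int(np.floor(cr)) + pad + 1
        c0, c1 = max(c0, 0), min(c1, w)
        r0, r1 = max(r0, 0), min(r1, h)
        if c0 >= c1 or r0 >= r1:
            continue
        gc, gr = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
        dist = np.hypot(gc - cc, gr - cr)
        cover = np.clip(r + 0.5 - dist, 0.0, 1.0)  # anti-aliased disc edge
        patch = frames[i, r0:r1, c0:c1]
        frames[i, r0:r1, c0:c1] = patch + (camera.foreground - camera.background) * cover
    if pixel_noise_sd > 0:
        frames = np.clip(frames + rng.normal(0.0, pixel_noise_sd, frames.shape), 0, 1)

    meta = {
        "seed": seed,
        "kind": "tunnel_video",
        "spec_hash": spec_hash(track.spec) if track.spec is not None else None,
        "px_per_mm": camera.px_per_mm,
    }
    return FrameSequence(frames=frames, fps=track.fps, metadata=meta)
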