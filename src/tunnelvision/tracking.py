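"""Digitising tunnel videos into calibrated flight tracks.

Detection is frame differencing: consecutive frames are subtracted, the
absolute difference is thresholded and the largest connected component is
taken as the moth's silhouette change.  The symmetric difference of two
silhouettes is centred on the *midpoint* of the two positions, so a
detection made from the pair (t-1, t) is timestamped t - 1/2;
:func:`assemble_track` resamples these half-frame positions onto integer
frame times (exact for locally linear motion).

The component area doubles as the height proxy: the camera sits below the
tunnel, so a larger silhouette means a lower flight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .frames import FrameSequence
from .specs import TUNNEL_HALF_WIDTH_MM, TUNNEL_LENGTH_MM

__all__ = [
    "Detection",
    "Calibration",
    "FlightTrack",
    "difference_segment",
    "detect_sequence",
    "assemble_tracks",
    "assemble_track",
    "filter_complete_flights",
]

#: Default binarisation threshold on |frame difference| (fraction of range).
DEFAULT_DIFF_THRESHOLD = 0.08
#: Default minimum accepted component area, px^2.
DEFAULT_MIN_AREA = 20


@dataclass(frozen=True)
class Detection:
    """One frame-differencing detection (possibly invalid)."""

    frame_index: int
    centroid: tuple[float, float] | None  # (col, row)
    area: float
    valid: bool

    @classmethod
    def invalid(cls, frame_index: int) -> "Detection":
        return cls(frame_index=frame_index, centroid=None, area=0.0, valid=False)


@dataclass(frozen=True)
class Calibration:
    """Per-axis linear pixel-to-mm mapping for the bottom-mounted camera."""

    px_per_mm_x: float
    px_per_mm_y: float
    origin_col: float  # pixel column of x = 0 (tunnel entrance)
    midline_row: float  # pixel row of y = 0 (tunnel midline)

    def to_mm(self, col, row):
        x = (np.asarray(col) - self.origin_col) / self.px_per_mm_x
        y = (self.midline_row - np.asarray(row)) / self.px_per_mm_y
        return x, y


@dataclass
class FlightTrack:
    """Calibrated track of one tunnel traversal.

    ``data`` columns: frame, x_mm, y_mm, area_px2, interpolated.
    """

    data: pd.DataFrame
    fps: float
    calibration: Calibration | None = None
    condition_id: str = ""

    def __post_init__(self) -> None:
        if len(self.data) < 2:
            raise ValueError("a flight track needs >= 2 records")
        t = self.data["frame"].to_numpy()
        if not (np.diff(t) > 0).all():
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_arrays(
        cls,
        x_mm,
        y_mm,
        fps: float = 50.0,
        area_px2=None,
        interpolated=None,
        condition_id: str = "",
    ) -> "FlightTrack":
        """Build a track directly from coordinate arrays (bypassing video)."""
        x = np.asarray(x_mm, dtype=float)
        n = len(x)
        df = pd.DataFrame(
            {
                "frame": np.arange(n),
                "x_mm": x,
                "y_mm": np.asarray(y_mm, dtype=float),
                "area_px2": np.zeros(n) if area_px2 is None else np.asarray(area_px2, float),
                "interpolated": np.zeros(n, bool)
                if interpolated is None
                else np.asarray(interpolated, bool),
            }
        )
        return cls(data=df, fps=fps, condition_id=condition_id)

    @classmethod
    def from_ground_truth(cls, sim, condition_id: str = "") -> "FlightTrack":
        """Wrap a :class:`~tunnelvision.synthetic.SimulatedTrack` as a track."""
        return cls.from_arrays(
            sim.data["x_mm"],
            sim.data["y_mm"],
            fps=sim.fps,
            condition_id=condition_id,
        )

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def difference_segment(
    prev_frame: np.ndarray,
    frame: np.ndarray,
    diff_threshold: float = DEFAULT_DIFF_THRESHOLD,
    min_area: float = DEFAULT_MIN_AREA,
    frame_index: int = 0,
    close_mask: bool = True,
) -> Detection:
    """Detect the moving animal in one frame pair.

    The binary difference mask is labelled with 8-connectivity and the
    largest component of at least ``min_area`` px^2 wins; its unweighted
    pixel centroid and area form the detection.  A 3x3 binary closing
    (default on) joins the two crescents of the silhouettes' symmetric
    difference, which otherwise may touch only diagonally.  Components of
    equal area are tie-broken by the smaller bounding-box top row.
    """
    prev_frame = np.asarray(prev_frame, dtype=float)
    frame = np.asarray(frame, dtype=float)
    if prev_frame.shape != frame.shape:
        raise ValueError("frames must have identical dimensions")
    mask = np.abs(frame - prev_frame) > diff_threshold
    # closing joins the two crescents of the silhouettes' symmetric
    # difference for labelling, but area/centroid count only raw mask pixels
    support = (
        ndimage.binary_closing(mask, structure=np.ones((3, 3), bool))
        if close_mask
        else mask
    )
    labels = measure.label(support, connectivity=2)
    if labels.max() == 0:
        return Detection.invalid(frame_index)
    candidates = []
    for p in measure.regionprops(labels):
        rows_px, cols_px = np.nonzero(mask & (labels == p.label))
        if len(rows_px) >= min_area:
            candidates.append((len(rows_px), p.bbox[0], cols_px.mean(), rows_px.mean()))
    if not candidates:
        return Detection.invalid(frame_index)
    candidates.sort(key=lambda c: (-c[0], c[1]))
    area, _, col, row = candidates[0]
    return Detection(frame_index=frame_index, centroid=(col, row), area=float(area), valid=True)


def detect_sequence(
    seq: FrameSequence,
    diff_threshold: float = DEFAULT_DIFF_THRESHOLD,
    min_area: float = DEFAULT_MIN_AREA,
) -> list[Detection]:
    """Run :func:`difference_segment` over all consecutive frame pairs."""
    dets = []
    for i in range(1, len(seq)):
        dets.append(
            difference_segment(
                seq.frames[i - 1],
                seq.frames[i],
                diff_threshold=diff_threshold,
                min_area=min_area,
                frame_index=i,
            )
        )
    return dets


def _segment_to_track(
    dets: list[Detection],
    calibration: Calibration,
    fps: float,
    condition_id: str,
) -> FlightTrack | None:
    # detection from pair (t-1, t) sits at time t - 1/2
    times = np.array([d.frame_index - 0.5 for d in dets])
    cols = np.array([d.centroid[0] for d in dets])
    rows = np.array([d.centroid[1] for d in dets])
    areas = np.array([d.area for d in dets])
    frames = np.arange(int(np.ceil(times[0])), int(np.floor(times[-1])) + 1)
    if len(frames) < 2:
        return None
    col_i = np.interp(frames, times, cols)
    row_i = np.interp(frames, times, rows)
    # the symmetric-difference area is a noisy (quantised) silhouette-size
    # estimate; a short rolling median suppresses segmentation jitter while
    # preserving slow height changes
    areas = pd.Series(areas).rolling(5, center=True, min_periods=1).median().to_numpy()
    area_i = np.interp(frames, times, areas)
    # a frame is interpolated if its bracketing detections are > 1 frame apart
    right = np.searchsorted(times, frames)
    left = np.clip(right - 1, 0, len(times) - 1)
    right = np.clip(right, 0, len(times) - 1)
    interp = (times[right] - times[left]) > 1.0 + 1e-9
    x_mm, y_mm = calibration.to_mm(col_i, row_i)
    df = pd.DataFrame(
        {
            "frame": frames,
            "x_mm": np.clip(x_mm, 0.0, TUNNEL_LENGTH_MM),
            "y_mm": np.clip(y_mm, -TUNNEL_HALF_WIDTH_MM, TUNNEL_HALF_WIDTH_MM),
            "area_px2": area_i,
            "interpolated": interp,
        }
    )
    return FlightTrack(data=df, fps=fps, calibration=calibration, condition_id=condition_id)


def assemble_tracks(
    detections: Sequence[Detection],
    calibration: Calibration,
    fps: float,
    max_gap: int = 2,
    condition_id: str = "",
) -> list[FlightTrack]:
    """Assemble candidate tracks from a detection stream.

    Runs of missing detections up to ``max_gap`` frames are linearly
    interpolated (and flagged); longer runs split the stream into separate
    candidate tracks.
    """
    valid = [d for d in detections if d.valid]
    if len(valid) < 2:
        raise ValueError("no track: fewer than 2 valid detections")
    valid.sort(key=lambda d: d.frame_index)
    segments: list[list[Detection]] = [[valid[0]]]
    for d in valid[1:]:
        gap = d.frame_index - segments[-1][-1].frame_index - 1
        if gap > max_gap:
            segments.append([d])
        else:
            segments[-1].append(d)
    tracks = []
    for seg in segments:
        if len(seg) < 2:
            continue
        track = _segment_to_track(seg, calibration, fps, condition_id)
        if track is not None:
            tracks.append(track)
    if not tracks:
        raise ValueError("no track: no segment with 2+ detections")
    return tracks


def assemble_track(
    detections: Sequence[Detection],
    calibration: Calibration,
    fps: float,
    max_gap: int = 2,
    condition_id: str = "",
) -> FlightTrack:
    """Longest candidate track from :func:`assemble_tracks`."""
    tracks = assemble_tracks(detections, calibration, fps, max_gap, condition_id)
    return max(tracks, key=len)


def filter_complete_flights(
    tracks: Sequence[FlightTrack],
    tunnel_length_mm: float = TUNNEL_LENGTH_MM,
    entry_margin_mm: float = 100.0,
    exit_margin_mm: float = 100.0,
    backtrack_tol_mm: float = 50.0,
) -> list[FlightTrack]:
    """Keep only complete, monotone tunnel traversals.

    A track qualifies if it starts below the entry margin, ends beyond
    ``tunnel_length - exit_margin`` and never backtracks by more than
    ``backtrack_tol_mm`` against its net direction.  Accepted tracks are
    normalised to run 0 -> ``tunnel_length`` (reverse traversals are
    x-mirrored).
    """
    accepted = []
    for track in tracks:
        x = track.data["x_mm"].to_numpy()
        direction = np.sign(x[-1] - x[0])
        if direction == 0:
            continue
        xd = x * direction if direction > 0 else (tunnel_length_mm - x)
        if xd.min() > entry_margin_mm or xd.max() < tunnel_length_mm - exit_margin_mm:
            continue
        # largest excursion against the net direction
        reversal = np.max(np.maximum.accumulate(xd) - xd)
        if reversal > backtrack_tol_mm:
            continue
        if direction < 0:
            df = track.data.copy()
            df["x_mm"] = tunnel_length_mm - df["x_mm"]
            track = FlightTrack(
                data=df,
                fps=track.fps,
                calibration=track.calibration,
                condition_id=track.condition_id,
            )
        accepted.append(track)
    return accepted
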