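"""Multi-threshold contrast-edge scoring.

Edges are detected with a Prewitt gradient (kernels normalised so a unit
intensity step yields gradient magnitude 1) followed by non-maximum
suppression along the gradient direction, independently at each contrast
threshold of an increasing ladder (default 0.01, 0.025, 0.05, 0.1, 0.5).
Each edge pixel is then scored by the *highest* threshold at which it is
still detected — strong edges score 0.5, edges visible only at the most
permissive setting score 0.01, non-edges score 0.  Per-video maps are the
temporal mean of the per-frame score maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import filters

from .frames import FrameSequence
from .flow import QuadrantSummary, quadrant_mean

__all__ = [
    "DEFAULT_THRESHOLDS",
    "EdgeScoreMap",
    "prewitt_magnitude",
    "detect_edges",
    "edge_score_map",
    "edge_score_video",
    "edge_quadrant_mean",
]

DEFAULT_THRESHOLDS = (0.01, 0.025, 0.05, 0.1, 0.5)


def prewitt_magnitude(frame: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Prewitt gradient magnitude and components (gx along cols, gy along rows)."""
    frame = np.asarray(frame, dtype=float)
    # skimage's 1/3-normalised kernels give an intensity step of amplitude a
    # a gradient magnitude of exactly a, matching thresholds on the [0, 1]
    # intensity range
    gy = filters.prewitt_h(frame)  # d/drow
    gx = filters.prewitt_v(frame)  # d/dcol
    return np.hypot(gx, gy), gx, gy


def _nms(mag: np.ndarray, gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    """Thin the gradient magnitude: keep local maxima along the gradient.

    Directions are quantised to 4 bins (horizontal, vertical, two
    diagonals); a pixel survives if its magnitude is >= both neighbours
    along its gradient direction.
    """
    h, w = mag.shape
    padded = np.pad(mag, 1, mode="constant")
    ang = np.mod(np.degrees(np.arctan2(gy, gx)), 180.0)
    # neighbour offsets (drow, dcol) per quantised direction of the *gradient*
    bins = ((ang < 22.5) | (ang >= 157.5)) * 0 + ((ang >= 22.5) & (ang < 67.5)) * 1 + (
        (ang >= 67.5) & (ang < 112.5)
    ) * 2 + ((ang >= 112.5) & (ang < 157.5)) * 3
    offsets = {0: (0, 1), 1: (1, 1), 2: (1, 0), 3: (1, -1)}
    keep = np.zeros_like(mag, dtype=bool)
    rows, cols = np.indices(mag.shape)
    for b, (dr, dc) in offsets.items():
        sel = bins == b
        r, c = rows[sel] + 1, cols[sel] + 1
        m = padded[r, c]
        keep_sel = (m >= padded[r + dr, c + dc]) & (m >= padded[r - dr, c - dc])
        keep[sel] = keep_sel
    return keep


def detect_edges(frame: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean edge map at one contrast threshold (Prewitt + thinning)."""
    mag, gx, gy = prewitt_magnitude(frame)
    return _nms(mag, gx, gy) & (mag >= threshold)


@dataclass
class EdgeScoreMap:
    """Per-pixel edge scores; values restricted to {0} union the threshold set."""

    scores: np.ndarray
    thresholds: tuple[float, ...]
    metadata: dict = field(default_factory=dict)


def edge_score_map(
    frame: np.ndarray, thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
) -> EdgeScoreMap:
    """Score each pixel by the highest threshold at which it is an edge.

    Equivalent to running :func:`detect_edges` at every threshold and
    taking the largest detecting threshold per pixel (0 where none detect).
    """
    thresholds = tuple(thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])) or not thresholds:
        raise ValueError("thresholds must be strictly increasing and non-empty")
    frame = np.asarray(frame, dtype=float)
    if frame.min() < -1e-9 or frame.max() > 1 + 1e-9:
        raise ValueError("frame intensities must be in [0, 1]")
    mag, gx, gy = prewitt_magnitude(frame)
    thin = _nms(mag, gx, gy)
    scores = np.zeros_like(mag)
    for t in thresholds:  # increasing: later passes overwrite with higher scores
        scores[thin & (mag >= t)] = t
    return EdgeScoreMap(scores=scores, thresholds=thresholds)


def edge_score_video(
    frames: FrameSequence | np.ndarray,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> EdgeScoreMap:
    """Temporal mean of per-frame edge-score maps over a whole video."""
    stack = frames.frames if isinstance(frames, FrameSequence) else np.asarray(frames)
    maps = [edge_score_map(f, thresholds).scores for f in stack]
    return EdgeScoreMap(
        scores=np.mean(maps, axis=0),
        thresholds=tuple(thresholds),
        metadata={"n_frames": len(maps), "temporal_mean": True},
    )


def edge_quadrant_mean(
    edge_map: EdgeScoreMap,
    masks: dict[str, np.ndarray],
    combine_lateral: bool = False,
) -> QuadrantSummary:
    """Sector means of an edge-score map (see :func:`~tunnelvision.flow.quadrant_mean`)."""
    return quadrant_mean(edge_map.scores, masks, combine_lateral=combine_lateral)
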