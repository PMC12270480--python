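"""Translational optic-flow quantification per visual-field quadrant.

Pipeline: dense per-pixel flow between consecutive frames -> radial
("translational") filter around the focus of expansion -> per-pixel
temporal mean magnitude -> mean per 90-degree visual-field sector
(dorsal / ventral / left / right).

The dense estimator is pluggable behind a fixed contract: it receives two
frames and returns a per-pixel (u, v) displacement in px/frame, where u is
along columns and v along rows and (u, v) is the image motion of scene
features from the first to the second frame.  The default is the iterative
Lucas-Kanade solver; TV-L1 is available for higher accuracy at higher
cost.  The estimator name and parameters are recorded in the output
metadata of every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from skimage import registration

from .frames import FrameSequence

__all__ = [
    "FlowEstimator",
    "TranslationalFlowMap",
    "QuadrantSummary",
    "estimate_dense_flow",
    "translational_filter",
    "temporal_mean_magnitude",
    "quadrant_masks",
    "quadrant_mean",
    "scene_flow_summary",
]

QUADRANTS = ("dorsal", "ventral", "left", "right")

#: Pixels closer than this to the FOE are excluded (radial direction undefined).
FOE_EXCLUSION_PX = 5.0
#: Default angular tolerance around the outward radial direction, degrees.
DEFAULT_ANGLE_TOL_DEG = 30.0
#: Rim margin (px) excluded from quadrant pooling: dense window-based
#: estimators are invalid where their support crosses the image-circle
#: boundary into the static background of synthetic fisheye frames.
RIM_MARGIN_PX = 8.0


def _ilk(frame0: np.ndarray, frame1: np.ndarray, **params) -> np.ndarray:
    params.setdefault("radius", 5)
    params.setdefault("gaussian", False)
    flow = registration.optical_flow_ilk(frame0, frame1, **params)
    # skimage returns (row, col) components; stack as (u, v) = (col, row)
    return np.stack([flow[1], flow[0]], axis=-1)


def _tvl1(frame0: np.ndarray, frame1: np.ndarray, **params) -> np.ndarray:
    flow = registration.optical_flow_tvl1(frame0, frame1, **params)
    return np.stack([flow[1], flow[0]], axis=-1)


ESTIMATORS: dict[str, Callable] = {"ilk": _ilk, "tvl1": _tvl1}


@dataclass(frozen=True)
class FlowEstimator:
    """Named dense-flow estimator with fixed parameters (recorded in outputs)."""

    name: str = "ilk"
    params: dict = field(default_factory=dict)

    def __call__(self, frame0: np.ndarray, frame1: np.ndarray) -> np.ndarray:
        try:
            fn = ESTIMATORS[self.name]
        except KeyError:
            raise ValueError(f"unknown flow estimator {self.name!r}") from None
        return fn(frame0, frame1, **self.params)


def estimate_dense_flow(
    frames: FrameSequence | np.ndarray,
    estimator: FlowEstimator | None = None,
) -> np.ndarray:
    """Dense flow fields for all consecutive frame pairs.

    Returns an array of shape (T-1, H, W, 2) of (u, v) displacements in
    px/frame.
    """
    stack = frames.frames if isinstance(frames, FrameSequence) else np.asarray(frames)
    if len(stack) < 2:
        raise ValueError("need >= 2 frames to estimate flow")
    estimator = estimator or FlowEstimator()
    return np.stack(
        [estimator(stack[i], stack[i + 1]) for i in range(len(stack) - 1)]
    )


def translational_filter(
    field_uv: np.ndarray,
    foe: tuple[float, float] | None = None,
    angle_tol_deg: float = DEFAULT_ANGLE_TOL_DEG,
    foe_exclusion_px: float = FOE_EXCLUSION_PX,
) -> np.ndarray:
    """Keep only flow vectors radially oriented away from the FOE.

    A vector survives if its direction deviates from the outward radial
    direction at its pixel by at most ``angle_tol_deg``; all others are set
    to zero, as are pixels within ``foe_exclusion_px`` of the FOE where the
    radial direction is undefined.  Works on a single (H, W, 2) field or a
    (T, H, W, 2) stack.
    """
    field_uv = np.asarray(field_uv, dtype=float)
    if field_uv.ndim == 4:
        return np.stack(
            [
                translational_filter(f, foe, angle_tol_deg, foe_exclusion_px)
                for f in field_uv
            ]
        )
    h, w = field_uv.shape[:2]
    cx, cy = ((w - 1) / 2.0, (h - 1) / 2.0) if foe is None else foe
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError("FOE must lie inside the image")
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    rx, ry = cols - cx, rows - cy
    rho = np.hypot(rx, ry)
    mag = np.hypot(field_uv[..., 0], field_uv[..., 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_dev = (field_uv[..., 0] * rx + field_uv[..., 1] * ry) / (mag * rho)
    keep = cos_dev >= np.cos(np.deg2rad(angle_tol_deg))
    keep &= rho > foe_exclusion_px
    keep &= mag > 0
    return np.where(keep[..., None], field_uv, 0.0)


@dataclass
class TranslationalFlowMap:
    """Per-pixel temporal-mean magnitude of filtered (translational) flow."""

    magnitude: np.ndarray  # (H, W), px/frame
    mask: np.ndarray  # in-circle pixels
    metadata: dict = field(default_factory=dict)


def temporal_mean_magnitude(
    filtered_fields: np.ndarray,
    mask: np.ndarray | None = None,
    include_rejected_as_zero: bool = True,
    metadata: dict | None = None,
) -> TranslationalFlowMap:
    """Per-pixel mean magnitude over all frame pairs.

    With ``include_rejected_as_zero`` (default) rejected vectors count as
    zeros, so the map is the mean magnitude over the whole video; the
    alternative averages only over frame pairs where the pixel carried a
    surviving vector.
    """
    fields = np.asarray(filtered_fields, dtype=float)
    if fields.ndim == 3:
        fields = fields[None]
    if len(fields) < 1:
        raise ValueError("need at least one flow field")
    mags = np.hypot(fields[..., 0], fields[..., 1])
    if include_rejected_as_zero:
        mean = mags.mean(axis=0)
    else:
        kept = mags > 0
        with np.errstate(invalid="ignore"):
            mean = np.where(
                kept.any(axis=0), mags.sum(axis=0) / np.maximum(kept.sum(axis=0), 1), 0.0
            )
    h, w = mean.shape
    if mask is None:
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        cols, rows = np.meshgrid(np.arange(w), np.arange(h))
        mask = np.hypot(cols - cx, rows - cy) <= min(w, h) / 2.0
    mean = np.where(mask, mean, 0.0)
    return TranslationalFlowMap(magnitude=mean, mask=mask, metadata=metadata or {})


def quadrant_masks(
    width: int,
    height: int,
    center: tuple[float, float] | None = None,
    radius: float | None = None,
) -> dict[str, np.ndarray]:
    """Four 90-degree sector masks partitioning the image circle.

    Sectors are bounded by the +-45 degree diagonals.  With angles measured
    anticlockwise from the +x image axis (dorsal = up = decreasing row):
    [-45, 45) right, [45, 135) dorsal, [135, 225) left, [225, 315) ventral.
    """
    cx, cy = ((width - 1) / 2.0, (height - 1) / 2.0) if center is None else center
    if radius is None:
        radius = min(width, height) / 2.0
    cols, rows = np.meshgrid(np.arange(width), np.arange(height))
    in_circle = np.hypot(cols - cx, rows - cy) <= radius
    ang = np.degrees(np.arctan2(cy - rows, cols - cx))  # up = +90
    ang = np.mod(ang + 45.0, 360.0)  # right sector now [0, 90)
    sector = (ang // 90.0).astype(int)
    order = ("right", "dorsal", "left", "ventral")
    return {name: in_circle & (sector == i) for i, name in enumerate(order)}


@dataclass(frozen=True)
class QuadrantSummary:
    """Mean magnitude (flow or edge score) in each visual-field sector."""

    means: dict
    n_pixels: dict
    lateral_combined: float | None = None

    def as_dict(self) -> dict:
        out = {f"{q}_mean": self.means[q] for q in QUADRANTS}
        if self.lateral_combined is not None:
            out["lateral_combined_mean"] = self.lateral_combined
        return out


def quadrant_mean(
    value_map: np.ndarray | TranslationalFlowMap,
    masks: dict[str, np.ndarray],
    combine_lateral: bool = False,
) -> QuadrantSummary:
    """Arithmetic mean of a per-pixel map in each sector.

    ``combine_lateral`` additionally reports the area-weighted mean of the
    left and right sectors (used for natural scenes, where the two lateral
    quadrants are pooled; tunnel analyses keep them separate).
    """
    arr = value_map.magnitude if isinstance(value_map, TranslationalFlowMap) else np.asarray(value_map)
    means, n_pixels = {}, {}
    for name, mask in masks.items():
        if not mask.any():
            raise ValueError(f"empty quadrant mask {name!r}")
        means[name] = float(arr[mask].mean())
        n_pixels[name] = int(mask.sum())
    lateral = None
    if combine_lateral:
        n_lat = n_pixels["left"] + n_pixels["right"]
        lateral = (
            means["left"] * n_pixels["left"] + means["right"] * n_pixels["right"]
        ) / n_lat
    return QuadrantSummary(means=means, n_pixels=n_pixels, lateral_combined=lateral)


def scene_flow_summary(
    frames: FrameSequence,
    estimator: FlowEstimator | None = None,
    angle_tol_deg: float = DEFAULT_ANGLE_TOL_DEG,
    combine_lateral: bool = False,
    rim_margin_px: float = RIM_MARGIN_PX,
) -> tuple[TranslationalFlowMap, QuadrantSummary]:
    """End-to-end translational-flow quadrant summary of one video.

    Quadrant pooling excludes an outer annulus of ``rim_margin_px`` where
    the dense estimator's window support crosses the synthetic image-circle
    boundary; use 0 to pool over the full circle.
    """
    estimator = estimator or FlowEstimator()
    fields = estimate_dense_flow(frames, estimator)
    filtered = translational_filter(fields, angle_tol_deg=angle_tol_deg)
    meta = {
        "estimator": estimator.name,
        "estimator_params": dict(estimator.params),
        "angle_tol_deg": angle_tol_deg,
        "rim_margin_px": rim_margin_px,
    }
    fmap = temporal_mean_magnitude(filtered, metadata=meta)
    h, w = fmap.magnitude.shape
    masks = quadrant_masks(w, h, radius=min(w, h) / 2.0 - rim_margin_px)
    return fmap, quadrant_mean(fmap, masks, combine_lateral=combine_lateral)
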