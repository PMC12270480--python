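"""Parameterised descriptions of synthetic worlds.

Every generator in :mod:`tunnelvision.synthetic` is driven by one of the
frozen spec dataclasses below.  A spec plus its ``seed`` fully determines
the generated artefact (frames, tracks, tables), which is what makes the
whole pipeline testable without any real recordings.

Coordinate conventions
----------------------
Tunnel frame: ``x`` runs 0–1000 mm from the entrance, ``y`` is the signed
lateral offset from the midline (positive towards the left wall, range
±150 mm), ``z`` is height above the floor (0–300 mm).  Positions are
continuous millimetres; pixels only appear at render time.

Fisheye camera frame: the camera looks along its travel direction, so the
focus of expansion sits at the image centre.  "Dorsal" is up in display
coordinates (decreasing row index).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "TexturedPlane",
    "SceneSpec",
    "TrajectorySpec",
    "PatternSpec",
    "StatsDesign",
    "spec_hash",
    "save_spec",
    "load_spec",
]

PLANE_ORIENTATIONS = ("floor", "ceiling", "left_wall", "right_wall", "end_wall")
TEXTURES = ("stripes", "checker", "noise", "uniform")
TRAJECTORY_REGIMES = (
    "straight_centred",
    "offset_straight",
    "diagonal_cross",
    "oscillating",
    "piecewise",
)
PATTERN_KINDS = (
    "grating_perpendicular",
    "grating_parallel",
    "single_stripe",
    "switching_stripe",
    "checkerboard",
    "none",
)

#: Tunnel interior dimensions in mm (length x width x height).
TUNNEL_LENGTH_MM = 1000.0
TUNNEL_HALF_WIDTH_MM = 150.0
TUNNEL_HEIGHT_MM = 300.0


@dataclass(frozen=True)
class TexturedPlane:
    """One infinite textured plane of a synthetic scene.

    Parameters
    ----------
    distance_mm:
        Perpendicular distance from the camera path to the plane; must be
        positive.
    orientation:
        Which side of the camera the plane sits on; one of
        ``floor, ceiling, left_wall, right_wall, end_wall``.
    texture:
        Procedural pattern id (``stripes``, ``checker``, ``noise`` or
        ``uniform``).
    contrast:
        Peak-to-mean amplitude of the pattern around mid-grey, in [0, 1].
    period_mm:
        Spatial period of the pattern on the plane.
    """

    distance_mm: float
    orientation: str
    texture: str = "noise"
    contrast: float = 0.8
    period_mm: float = 100.0

    def __post_init__(self) -> None:
        if self.distance_mm <= 0:
            raise ValueError("plane distance must be > 0")
        if self.orientation not in PLANE_ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.texture not in TEXTURES:
            raise ValueError(f"unknown texture {self.texture!r}")
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must be in [0, 1]")
        if self.period_mm <= 0:
            raise ValueError("texture period must be > 0")


@dataclass(frozen=True)
class SceneSpec:
    """A forward-translating fisheye camera in a world of textured planes.

    Defaults mirror the natural-scene imaging rig: 12 mm/s forward travel,
    185 degree fisheye, 30 frames per second.
    """

    planes: tuple[TexturedPlane, ...]
    camera_speed: float = 12.0  # mm/s
    fps: float = 30.0
    duration: float = 2.0  # s
    fov_deg: float = 185.0
    image_size: tuple[int, int] = (200, 200)  # (W, H)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "planes", tuple(self.planes))
        if not 0.0 < self.fov_deg <= 185.0:
            raise ValueError("fov_deg must be in (0, 185]")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        w, h = self.image_size
        if w <= 0 or h <= 0:
            raise ValueError("image dimensions must be positive")
        if self.camera_speed < 0:
            raise ValueError("camera_speed must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration))


@dataclass(frozen=True)
class TrajectorySpec:
    """Parameterised moth trajectory through the tunnel.

    ``regime`` semantics:

    - ``straight_centred``: y = 0 throughout.
    - ``offset_straight``: y = entry_offset_mm throughout.
    - ``diagonal_cross``: y holds the entry offset over the first third of
      the tunnel, moves linearly to the exit offset across the central
      third (mirroring the side-switching stripe stimulus), then holds.
    - ``oscillating``: sinusoidal y around the midline with the given
      amplitude and spatial period.
    - ``piecewise``: linear ramp from entry to exit offset over the whole
      tunnel length.
    """

    regime: str = "straight_centred"
    entry_offset_mm: float = 0.0
    exit_offset_mm: float = 0.0
    oscillation_amplitude_mm: float = 0.0
    oscillation_period_mm: float = 500.0
    speed_mm_s: float = 400.0  # typical tunnel traversal speed
    height_mm: float = 150.0
    height_amplitude_mm: float = 0.0
    height_profile: str = "sine"  # "sine": one cycle over the tunnel; "ramp": linear
    noise_sd_mm: float = 0.0
    fps: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in TRAJECTORY_REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        for off in (self.entry_offset_mm, self.exit_offset_mm):
            if abs(off) > TUNNEL_HALF_WIDTH_MM:
                raise ValueError("lateral offset outside tunnel half-width")
        if abs(self.oscillation_amplitude_mm) > TUNNEL_HALF_WIDTH_MM:
            raise ValueError("oscillation amplitude outside tunnel half-width")
        if self.speed_mm_s <= 0:
            raise ValueError("speed must be > 0")
        if self.noise_sd_mm < 0:
            raise ValueError("noise sd must be >= 0")
        if not 0.0 <= self.height_mm <= TUNNEL_HEIGHT_MM:
            raise ValueError("height outside tunnel")
        if self.height_profile not in ("sine", "ramp"):
            raise ValueError(f"unknown height profile {self.height_profile!r}")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")


@dataclass(frozen=True)
class PatternSpec:
    """A tunnel stimulus pattern on one side of the tunnel."""

    side: str
    kind: str
    stripe_width_mm: float = 30.0
    period_mm: float = 60.0
    coverage: float = 1.0
    contrast: float = 1.0
    condition_id: str = ""

    def __post_init__(self) -> None:
        if self.side not in ("floor", "ceiling", "left", "right"):
            raise ValueError(f"unknown side {self.side!r}")
        if self.kind not in PATTERN_KINDS:
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        striped = self.kind in (
            "grating_perpendicular",
            "grating_parallel",
            "single_stripe",
            "switching_stripe",
        )
        if striped and self.stripe_width_mm <= 0:
            raise ValueError("stripe_width must be > 0 for striped patterns")
        if not 0.0 < self.coverage <= 1.0:
            raise ValueError("coverage must be in (0, 1]")
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must be in [0, 1]")


@dataclass(frozen=True)
class StatsDesign:
    """Design description for the grouped-magnitude statistics layer."""

    response: str = "magnitude"
    habitats: tuple[str, ...] = ("open", "semi", "closed")
    quadrants: tuple[str, ...] = ("ventral", "lateral", "dorsal")
    random_group: str = "scene"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "habitats", tuple(self.habitats))
        object.__setattr__(self, "quadrants", tuple(self.quadrants))
        if len(self.habitats) < 2 or len(self.quadrants) < 2:
            raise ValueError("need >= 2 levels per tested factor")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


# ---------------------------------------------------------------------------
# Serialisation helpers


def _to_jsonable(spec: Any) -> Any:
    if dataclasses.is_dataclass(spec) and not isinstance(spec, type):
        return {
            "__type__": type(spec).__name__,
            **{
                f.name: _to_jsonable(getattr(spec, f.name))
                for f in dataclasses.fields(spec)
            },
        }
    if isinstance(spec, (list, tuple)):
        return [_to_jsonable(v) for v in spec]
    return spec


_SPEC_TYPES = {}


def _register_types() -> None:
    for cls in (TexturedPlane, SceneSpec, TrajectorySpec, PatternSpec, StatsDesign):
        _SPEC_TYPES[cls.__name__] = cls


def _from_jsonable(obj: Any) -> Any:
    if isinstance(obj, dict) and "__type__" in obj:
        cls = _SPEC_TYPES[obj["__type__"]]
        kwargs = {k: _from_jsonable(v) for k, v in obj.items() if k != "__type__"}
        for f in dataclasses.fields(cls):
            if f.name in kwargs and isinstance(kwargs[f.name], list):
                kwargs[f.name] = tuple(kwargs[f.name])
        return cls(**kwargs)
    if isinstance(obj, list):
        return [_from_jsonable(v) for v in obj]
    return obj


def spec_hash(spec: Any) -> str:
    """Stable short hash of a spec, used to tag generated artefacts."""
    payload = json.dumps(_to_jsonable(spec), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def save_spec(spec: Any, path: str | Path) -> None:
    """Write a spec as a flat YAML (or JSON, by extension) config file."""
    path = Path(path)
    data = _to_jsonable(spec)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_spec(path: str | Path) -> Any:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return _from_jsonable(data)


_register_types()
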