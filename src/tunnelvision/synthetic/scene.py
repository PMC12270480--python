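"""Fisheye rendering of forward camera translation through textured scenes.

The camera follows the natural-scene imaging rig: it translates along its
own optical axis, so the focus of expansion (FOE) coincides with the image
centre.  The lens is modelled as an ideal equidistant fisheye
(``rho = f * theta``), the simplest projection with an exact closed-form
translational flow field; the real lens's projection is not documented, so
this is an explicit modelling assumption.

For a scene point whose ray leaves the optical axis by eccentricity
``theta`` and whose perpendicular distance from the camera path is ``d``,
forward translation at speed ``v`` produces an angular image speed

    omega = v * sin(theta)**2 / d        [rad/s]

directed exactly radially away from the FOE.  Under the equidistant
projection this maps to a pixel speed ``f_px * omega``.  The renderer and
:func:`analytic_translational_flow` share the same geometry, so rendered
sequences come with an exact flow oracle.
"""

from __future__ import annotations

import numpy as np

from ..frames import FrameSequence
from ..specs import SceneSpec, TexturedPlane, spec_hash

__all__ = [
    "render_fisheye_sequence",
    "analytic_translational_flow",
    "analytic_flow_map",
    "focal_length_px",
    "image_circle_mask",
]

#: Sub-pixel supersampling factor (2x2 grid) used to suppress spatial aliasing.
SUPERSAMPLE = 2


def focal_length_px(scene: SceneSpec) -> float:
    """Equidistant focal length so that ``fov_deg`` fills the image circle."""
    w, h = scene.image_size
    radius = min(w, h) / 2.0
    return radius / np.deg2rad(scene.fov_deg / 2.0)


def image_circle_mask(scene: SceneSpec) -> np.ndarray:
    """Boolean (H, W) mask of pixels inside the fisheye image circle."""
    w, h = scene.image_size
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    rho = np.hypot(cols - cx, rows - cy)
    return rho <= min(w, h) / 2.0


def _ray_directions(scene: SceneSpec, col: np.ndarray, row: np.ndarray):
    """Unit ray directions (X right, Y up, Z forward) for pixel coordinates.

    Returns (dirs, theta, valid) where ``valid`` marks pixels inside the
    image circle whose eccentricity does not exceed half the field of view.
    """
    w, h = scene.image_size
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    f = focal_length_px(scene)
    dx = col - cx
    dy = cy - row  # row index grows downwards; camera Y is up
    rho = np.hypot(dx, dy)
    theta = rho / f
    valid = (rho <= min(w, h) / 2.0 + 1e-9) & (theta <= np.pi)
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(rho > 0, dx / rho, 1.0)
        uy = np.where(rho > 0, dy / rho, 0.0)
    sin_t, cos_t = np.sin(theta), np.cos(theta)
    dirs = np.stack([sin_t * ux, sin_t * uy, cos_t], axis=-1)
    return dirs, theta, valid


def _intersect_plane(
    plane: TexturedPlane, dirs: np.ndarray, z_cam: float
) -> tuple[np.ndarray, np.ndarray]:
    """Ray parameter t (mm) for each pixel ray, inf where the ray misses."""
    dx, dy, dz = dirs[..., 0], dirs[..., 1], dirs[..., 2]
    d = plane.distance_mm
    with np.errstate(divide="ignore", invalid="ignore"):
        if plane.orientation == "floor":
            t = -d / dy
        elif plane.orientation == "ceiling":
            t = d / dy
        elif plane.orientation == "left_wall":
            t = -d / dx
        elif plane.orientation == "right_wall":
            t = d / dx
        elif plane.orientation == "end_wall":
            t = (d - z_cam) / dz
        else:  # pragma: no cover - validated by the spec
            raise ValueError(plane.orientation)
    t = np.where(np.isfinite(t) & (t > 1e-9), t, np.inf)
    return t, t < np.inf


def _lattice_hash(ix: np.ndarray, iy: np.ndarray, seed: int) -> np.ndarray:
    """Deterministic pseudo-random values in [0, 1) on an integer lattice."""
    v = np.sin(ix * 127.1 + iy * 311.7 + seed * 74.7) * 43758.5453123
    return v - np.floor(v)


def _value_noise(u: np.ndarray, v: np.ndarray, period: float, seed: int) -> np.ndarray:
    """Smooth seeded value noise with correlation length ``period``."""
    gu, gv = u / period, v / period
    iu, iv = np.floor(gu), np.floor(gv)
    fu, fv = gu - iu, gv - iv
    # smoothstep interpolation keeps the field C1, avoiding lattice artefacts
    su = fu * fu * (3 - 2 * fu)
    sv = fv * fv * (3 - 2 * fv)
    n00 = _lattice_hash(iu, iv, seed)
    n10 = _lattice_hash(iu + 1, iv, seed)
    n01 = _lattice_hash(iu, iv + 1, seed)
    n11 = _lattice_hash(iu + 1, iv + 1, seed)
    top = n00 * (1 - su) + n10 * su
    bot = n01 * (1 - su) + n11 * su
    return top * (1 - sv) + bot * sv


def _texture_value(plane: TexturedPlane, u: np.ndarray, v: np.ndarray, seed: int):
    """Evaluate the plane's procedural texture at in-plane coords (u, v) mm.

    ``v`` is the coordinate parallel to the travel direction where that is
    in-plane (floor/ceiling/walls), so ``stripes`` are perpendicular to
    travel and sweep past the camera.
    """
    c, p = plane.contrast, plane.period_mm
    if plane.texture == "uniform":
        return np.full_like(u, 0.5)
    if plane.texture == "stripes":
        return 0.5 + 0.5 * c * np.sin(2 * np.pi * v / p)
    if plane.texture == "checker":
        return 0.5 + 0.5 * c * np.sin(2 * np.pi * u / p) * np.sin(2 * np.pi * v / p)
    if plane.texture == "noise":
        return 0.5 + c * (_value_noise(u, v, p, seed) - 0.5)
    raise ValueError(plane.texture)  # pragma: no cover


def _plane_uv(plane: TexturedPlane, point: np.ndarray):
    """In-plane texture coordinates of world intersection points."""
    px, py, pz = point[..., 0], point[..., 1], point[..., 2]
    if plane.orientation in ("floor", "ceiling"):
        return px, pz
    if plane.orientation in ("left_wall", "right_wall"):
        return py, pz
    return px, py  # end_wall


def _shade(scene: SceneSpec, dirs: np.ndarray, valid: np.ndarray, z_cam: float):
    """Colour each ray by its nearest plane's texture; 0.5 background."""
    best_t = np.full(dirs.shape[:-1], np.inf)
    img = np.full(dirs.shape[:-1], 0.5)
    for k, plane in enumerate(scene.planes):
        t, hit = _intersect_plane(plane, dirs, z_cam)
        closer = hit & (t < best_t)
        if not closer.any():
            continue
        t_safe = np.where(closer, t, 0.0)
        point = dirs * t_safe[..., None]
        point[..., 2] += z_cam
        u, v = _plane_uv(plane, point)
        tex = _texture_value(plane, u, v, scene.seed * 977 + k)
        img = np.where(closer, tex, img)
        best_t = np.where(closer, t, best_t)
    img[~valid] = 0.5
    return img, best_t


def render_fisheye_sequence(scene: SceneSpec) -> FrameSequence:
    """Render the camera's forward translation through ``scene``.

    Returns a :class:`FrameSequence` of ``round(fps * duration)`` frames.
    Rendering is fully deterministic for a given spec (all texture
    randomness is a pure function of the seed), and each frame is averaged
    over a 2x2 sub-pixel grid to suppress spatial aliasing.
    """
    if not scene.planes:
        raise ValueError("empty scene")
    w, h = scene.image_size
    cols, rows = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))

    # Precompute ray geometry per sub-pixel offset; it is frame-independent.
    offsets = (np.arange(SUPERSAMPLE) + 0.5) / SUPERSAMPLE - 0.5
    ray_sets = []
    for oy in offsets:
        for ox in offsets:
            ray_sets.append(_ray_directions(scene, cols + ox, rows + oy))

    frames = np.empty((scene.n_frames, h, w))
    for i in range(scene.n_frames):
        z_cam = scene.camera_speed * i / scene.fps
        acc = np.zeros((h, w))
        for dirs, _theta, valid in ray_sets:
            img, _ = _shade(scene, dirs, valid, z_cam)
            acc += img
        frames[i] = acc / len(ray_sets)

    meta = {"spec_hash": spec_hash(scene), "seed": scene.seed, "kind": "fisheye_scene"}
    return FrameSequence(frames=frames, fps=scene.fps, metadata=meta)


def analytic_translational_flow(
    scene: SceneSpec, pixel: tuple[float, float]
) -> np.ndarray:
    """Exact translational flow vector (px/frame) at one pixel.

    ``pixel`` is (col, row).  The magnitude is
    ``f_px * (v / d) * sin(theta)**2 / fps`` with ``d`` the perpendicular
    distance from the camera path to the intersected scene point, and the
    direction is exactly radial away from the image centre (the FOE).

    Raises
    ------
    ValueError
        If the pixel lies outside the image circle or its ray intersects
        no scene plane.
    """
    col = np.atleast_1d(np.asarray(pixel[0], dtype=float))
    row = np.atleast_1d(np.asarray(pixel[1], dtype=float))
    dirs, theta, valid = _ray_directions(scene, col, row)
    if not valid.all():
        raise ValueError("pixel outside image circle")
    best_t = np.full(col.shape, np.inf)
    for plane in scene.planes:
        t, hit = _intersect_plane(plane, dirs, 0.0)
        best_t = np.where(hit & (t < best_t), t, best_t)
    # the FOE itself has zero flow whether or not its ray hits a plane
    if not np.isfinite(best_t[theta > 0]).all():
        raise ValueError("ray does not intersect any scene plane")
    best_t = np.where(theta > 0, best_t, 1.0)
    point = dirs * best_t[..., None]
    d_perp = np.hypot(point[..., 0], point[..., 1])
    f = focal_length_px(scene)
    with np.errstate(divide="ignore", invalid="ignore"):
        omega = scene.camera_speed * np.sin(theta) ** 2 / d_perp
    mag_px = np.where(theta > 0, f * omega / scene.fps, 0.0)

    w, h = scene.image_size
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    rho = np.hypot(col - cx, row - cy)
    with np.errstate(divide="ignore", invalid="ignore"):
        ur = np.where(rho > 0, (col - cx) / rho, 0.0)
        vr = np.where(rho > 0, (row - cy) / rho, 0.0)
    vec = np.stack([mag_px * ur, mag_px * vr], axis=-1)
    return vec[0] if np.isscalar(pixel[0]) or np.ndim(pixel[0]) == 0 else vec


def analytic_flow_map(scene: SceneSpec) -> np.ndarray:
    """Dense (H, W, 2) analytic translational flow; zero where no plane is hit."""
    w, h = scene.image_size
    cols, rows = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    dirs, theta, valid = _ray_directions(scene, cols, rows)
    best_t = np.full((h, w), np.inf)
    for plane in scene.planes:
        t, hit = _intersect_plane(plane, dirs, 0.0)
        best_t = np.where(hit & (t < best_t), t, best_t)
    point = dirs * np.where(np.isfinite(best_t), best_t, 0.0)[..., None]
    d_perp = np.hypot(point[..., 0], point[..., 1])
    f = focal_length_px(scene)
    with np.errstate(divide="ignore", invalid="ignore"):
        omega = scene.camera_speed * np.sin(theta) ** 2 / d_perp
    mag_px = f * omega / scene.fps
    mag_px = np.where(valid & np.isfinite(best_t) & (theta > 0), mag_px, 0.0)

    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    rho = np.hypot(cols - cx, rows - cy)
    with np.errstate(divide="ignore", invalid="ignore"):
        ur = np.where(rho > 0, (cols - cx) / rho, 0.0)
        vr = np.where(rho > 0, (rows - cy) / rho, 0.0)
    return np.stack([mag_px * ur, mag_px * vr], axis=-1)
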