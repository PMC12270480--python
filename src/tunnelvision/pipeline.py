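"""Reproducible end-to-end runs: config validation, condition registry,
stage orchestration and run manifests.

A run is described by a plain-dict (or YAML) config with optional stage
blocks; :func:`run_pipeline` executes the requested stages in dependency
order (simulate -> track -> metrics -> flow/edges -> stats), writes CSV
outputs, and records every written file in a :class:`RunManifest`.  Runs
are idempotent per seed: re-running an identical config yields
bit-identical CSVs, and existing stage outputs are reused unless
``force=True``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import flow as flowmod
from . import edges as edgemod
from .metrics import compute_track_metrics
from .specs import PatternSpec, SceneSpec, TexturedPlane, TrajectorySpec, spec_hash
from .stats import omnibus_and_posthoc, pairwise_brown_forsythe, residual_normality_gate
from .synthetic.flight import TunnelCamera, render_track_video, simulate_track
from .synthetic.scene import render_fisheye_sequence
from .tracking import Calibration, assemble_track, detect_sequence, filter_complete_flights

__all__ = [
    "ConditionRegistry",
    "RunManifest",
    "register_condition",
    "validate_config",
    "run_pipeline",
    "demo_config",
]

logger = logging.getLogger("tunnelvision")


# ---------------------------------------------------------------------------
# Condition registry


class ConditionRegistry:
    """Maps short condition identifiers to tunnel stimulus geometry.

    Identifiers mimic the letter-number labels used for tunnel stimuli
    (e.g. "G1" for a grating condition); entries shipped with demo configs
    are illustrative, not reconstructions of any real stimulus table.
    """

    def __init__(self) -> None:
        self._entries: dict[str, tuple[PatternSpec, ...]] = {}

    def __contains__(self, condition_id: str) -> bool:
        return condition_id in self._entries

    def get(self, condition_id: str) -> tuple[PatternSpec, ...]:
        return self._entries[condition_id]

    def register(self, condition_id: str, patterns) -> "ConditionRegistry":
        if isinstance(patterns, PatternSpec):
            patterns = (patterns,)
        patterns = tuple(patterns)
        if condition_id in self._entries:
            if self._entries[condition_id] == patterns:
                return self  # consistent re-registration is a no-op
            raise ValueError(
                f"condition {condition_id!r} already bound to a different stimulus"
            )
        self._entries[condition_id] = patterns
        return self

    def save(self, path) -> None:
        data = {
            cid: [
                {f: getattr(p, f) for f in (
                    "side", "kind", "stripe_width_mm", "period_mm",
                    "coverage", "contrast", "condition_id")}
                for p in specs
            ]
            for cid, specs in self._entries.items()
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def load(cls, path) -> "ConditionRegistry":
        reg = cls()
        data = yaml.safe_load(Path(path).read_text()) or {}
        for cid, specs in data.items():
            reg.register(cid, tuple(PatternSpec(**s) for s in specs))
        return reg


def register_condition(registry: ConditionRegistry, condition_id: str, patterns):
    """Functional wrapper around :meth:`ConditionRegistry.register`."""
    return registry.register(condition_id, patterns)


# ---------------------------------------------------------------------------
# Config handling


_TRAJECTORY_KEYS = {
    "regime", "entry_offset_mm", "exit_offset_mm", "oscillation_amplitude_mm",
    "oscillation_period_mm", "speed_mm_s", "height_mm", "height_amplitude_mm",
    "noise_sd_mm", "fps", "seed",
}
_PLANE_KEYS = {"distance_mm", "orientation", "texture", "contrast", "period_mm"}
_SCENE_KEYS = {
    "camera_speed", "fps", "duration", "fov_deg", "image_size", "seed", "planes",
}


def validate_config(config: dict, registry: ConditionRegistry | None = None) -> dict:
    """Validate a pipeline config against the documented schema.

    Raises ``ValueError`` (before any stage runs) on unknown keys, missing
    required fields, or references to unregistered condition ids.
    """
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    allowed_top = {"seed", "stages", "flights", "scenes", "stats", "registry"}
    unknown = set(config) - allowed_top
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in config or not isinstance(config["seed"], int):
        raise ValueError("config needs an integer 'seed'")
    stages = config.get("stages", ["flights", "metrics", "flow", "edges", "stats"])
    known_stages = {"flights", "metrics", "flow", "edges", "stats"}
    if set(stages) - known_stages:
        raise ValueError(f"unknown stages: {sorted(set(stages) - known_stages)}")
    for block in config.get("flights", []):
        missing = {"condition_id", "n_flights", "trajectory"} - set(block)
        if missing:
            raise ValueError(f"flight block missing keys: {sorted(missing)}")
        if registry is not None and block["condition_id"] not in registry:
            raise ValueError(f"unknown condition_id {block['condition_id']!r}")
        bad = set(block["trajectory"]) - _TRAJECTORY_KEYS
        if bad:
            raise ValueError(f"unknown trajectory keys: {sorted(bad)}")
        TrajectorySpec(**block["trajectory"])  # field-level validation
    for block in config.get("scenes", []):
        missing = {"scene_id", "scene"} - set(block)
        if missing:
            raise ValueError(f"scene block missing keys: {sorted(missing)}")
        sdict = dict(block["scene"])
        bad = set(sdict) - _SCENE_KEYS
        if bad:
            raise ValueError(f"unknown scene keys: {sorted(bad)}")
        planes = tuple(TexturedPlane(**p) for p in sdict.pop("planes", []))
        if not planes:
            raise ValueError(f"scene {block['scene_id']!r} has no planes")
        if "image_size" in sdict:
            sdict["image_size"] = tuple(sdict["image_size"])
        SceneSpec(planes=planes, **sdict)
    return config


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config_hash: str
    seed: int
    outputs: list = field(default_factory=list)
    stages_run: list = field(default_factory=list)
    failed_stage: str | None = None
    started: str = ""
    finished: str = ""

    def record(self, path: Path) -> None:
        self.outputs.append(str(path))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


# ---------------------------------------------------------------------------
# Stages


def _scene_spec_from_block(block: dict) -> SceneSpec:
    sdict = dict(block["scene"])
    planes = tuple(TexturedPlane(**p) for p in sdict.pop("planes", []))
    if "image_size" in sdict:
        sdict["image_size"] = tuple(sdict["image_size"])
    return SceneSpec(planes=planes, **sdict)


def _stage_flights(config, outdir, manifest):
    camera = TunnelCamera()
    calib = Calibration(
        px_per_mm_x=camera.px_per_mm,
        px_per_mm_y=camera.px_per_mm,
        origin_col=camera.origin_col,
        midline_row=(camera.image_size[1] - 1) / 2.0,
    )
    rows = []
    for block in config.get("flights", []):
        cid = block["condition_id"]
        for rep in range(block["n_flights"]):
            tspec = TrajectorySpec(
                **{**block["trajectory"], "seed": config["seed"] * 1000 + rep}
            )
            sim = simulate_track(tspec)
            video = render_track_video(sim, camera, seed=tspec.seed)
            dets = detect_sequence(video)
            track = assemble_track(dets, calib, fps=video.fps, condition_id=cid)
            accepted = filter_complete_flights([track])
            if not accepted:
                logger.warning("flight %s/%d rejected as incomplete", cid, rep)
                continue
            df = accepted[0].data.assign(condition_id=cid, flight=rep)
            rows.append(df)
    tracks_csv = outdir / "tracks.csv"
    pd.concat(rows, ignore_index=True).to_csv(tracks_csv, index=False)
    manifest.record(tracks_csv)


def _stage_metrics(config, outdir, manifest):
    from .tracking import FlightTrack

    tracks = pd.read_csv(outdir / "tracks.csv")
    rows = []
    for (cid, rep), df in tracks.groupby(["condition_id", "flight"]):
        track = FlightTrack(
            data=df[["frame", "x_mm", "y_mm", "area_px2", "interpolated"]].reset_index(
                drop=True
            ),
            fps=50.0,
            condition_id=cid,
        )
        m = compute_track_metrics(track)
        rows.append({**m.as_dict(), "flight": rep})
    out = outdir / "metrics.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    manifest.record(out)


def _stage_flow_edges(config, outdir, manifest, do_flow, do_edges):
    flow_rows, edge_rows = [], []
    for block in config.get("scenes", []):
        spec = _scene_spec_from_block(block)
        seq = render_fisheye_sequence(spec)
        h, w = seq.shape
        masks = flowmod.quadrant_masks(w, h)
        if do_flow:
            _, summary = flowmod.scene_flow_summary(seq, combine_lateral=True)
            flow_rows.append(
                {
                    "scene_id": block["scene_id"],
                    "habitat": block.get("habitat", ""),
                    "spec_hash": spec_hash(spec),
                    **summary.as_dict(),
                }
            )
        if do_edges:
            emap = edgemod.edge_score_video(seq)
            summary = edgemod.edge_quadrant_mean(emap, masks, combine_lateral=True)
            edge_rows.append(
                {
                    "scene_id": block["scene_id"],
                    "habitat": block.get("habitat", ""),
                    "spec_hash": spec_hash(spec),
                    **summary.as_dict(),
                }
            )
    if do_flow and flow_rows:
        out = outdir / "flow_quadrants.csv"
        pd.DataFrame(flow_rows).to_csv(out, index=False)
        manifest.record(out)
    if do_edges and edge_rows:
        out = outdir / "edge_quadrants.csv"
        pd.DataFrame(edge_rows).to_csv(out, index=False)
        manifest.record(out)


def _stage_stats(config, outdir, manifest):
    metrics = pd.read_csv(outdir / "metrics.csv")
    response = config.get("stats", {}).get("response", "median_lateral_position_mm")
    alpha = config.get("stats", {}).get("alpha", 0.05)
    values = metrics[response].to_numpy()
    groups = metrics["condition_id"].to_numpy()
    choice = residual_normality_gate(values, groups, alpha)
    result = omnibus_and_posthoc(values, groups, choice, alpha)
    omnibus = pd.DataFrame(
        [
            {
                "response": response,
                "test": result.test,
                "statistic": result.statistic,
                "p": result.p,
                "alpha": alpha,
                "choice": choice,
            }
        ]
    )
    out = outdir / "stats_omnibus.csv"
    omnibus.to_csv(out, index=False)
    manifest.record(out)
    out = outdir / "stats_pairwise.csv"
    result.pairwise_p.to_csv(out)
    manifest.record(out)
    bf_p, bf_letters = pairwise_brown_forsythe(values, groups, alpha)
    letters = pd.DataFrame(
        [
            {"condition_id": g, "letters": result.letters[g], "bf_letters": bf_letters[g]}
            for g in sorted(result.letters)
        ]
    )
    out = outdir / "stats_letters.csv"
    letters.to_csv(out, index=False)
    manifest.record(out)


def run_pipeline(
    config: dict,
    outdir,
    registry: ConditionRegistry | None = None,
    force: bool = False,
) -> RunManifest:
    """Execute the configured stages and return the run manifest.

    Stage outputs already present in ``outdir`` are reused (resume
    semantics) unless ``force`` is set.  The manifest lists every file the
    run wrote and the stage at which a failure occurred, if any.
    """
    config = validate_config(config, registry)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config_hash(config),
        seed=config["seed"],
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    stages = config.get("stages", ["flights", "metrics", "flow", "edges", "stats"])
    stage_outputs = {
        "flights": ["tracks.csv"],
        "metrics": ["metrics.csv"],
        "flow": ["flow_quadrants.csv"],
        "edges": ["edge_quadrants.csv"],
        "stats": ["stats_omnibus.csv", "stats_pairwise.csv", "stats_letters.csv"],
    }
    try:
        for stage in ("flights", "metrics", "flow", "edges", "stats"):
            if stage not in stages:
                continue
            existing = [outdir / f for f in stage_outputs[stage]]
            if not force and all(p.exists() for p in existing):
                logger.info("stage %s: reusing existing outputs", stage)
                for p in existing:
                    manifest.record(p)
                manifest.stages_run.append(f"{stage} (cached)")
                continue
            logger.info("stage %s: running", stage)
            if stage == "flights":
                _stage_flights(config, outdir, manifest)
            elif stage == "metrics":
                _stage_metrics(config, outdir, manifest)
            elif stage == "flow":
                _stage_flow_edges(config, outdir, manifest, True, False)
            elif stage == "edges":
                _stage_flow_edges(config, outdir, manifest, False, True)
            elif stage == "stats":
                _stage_stats(config, outdir, manifest)
            manifest.stages_run.append(stage)
    except Exception:
        manifest.failed_stage = stage
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest.save(outdir / "manifest.json")
        raise
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.save(outdir / "manifest.json")
    manifest.record(outdir / "manifest.json")
    return manifest


def demo_config(seed: int = 1) -> tuple[dict, ConditionRegistry]:
    """A small seeded end-to-end configuration with illustrative conditions."""
    registry = ConditionRegistry()
    registry.register(
        "G1",
        PatternSpec(side="left", kind="grating_perpendicular", stripe_width_mm=30,
                    period_mm=60, condition_id="G1"),
    )
    registry.register(
        "S1",
        PatternSpec(side="ceiling", kind="switching_stripe", stripe_width_mm=30,
                    condition_id="S1"),
    )
    registry.register(
        "C1",
        PatternSpec(side="left", kind="checkerboard", stripe_width_mm=13.9,
                    period_mm=27.8, condition_id="C1"),
    )
    config = {
        "seed": seed,
        "stages": ["flights", "metrics", "flow", "edges", "stats"],
        "flights": [
            {
                "condition_id": "G1",
                "n_flights": 6,
                "trajectory": {"regime": "offset_straight", "entry_offset_mm": -60.0,
                               "noise_sd_mm": 2.0},
            },
            {
                "condition_id": "S1",
                "n_flights": 6,
                "trajectory": {"regime": "diagonal_cross", "entry_offset_mm": -80.0,
                               "exit_offset_mm": 80.0, "noise_sd_mm": 2.0},
            },
            {
                "condition_id": "C1",
                "n_flights": 6,
                "trajectory": {"regime": "straight_centred", "noise_sd_mm": 2.0},
            },
        ],
        "scenes": [
            {
                "scene_id": "demo_ground",
                "habitat": "open",
                "scene": {
                    "camera_speed": 600.0,
                    "fps": 30.0,
                    "duration": 0.3,
                    "image_size": [160, 160],
                    "seed": seed,
                    "planes": [
                        {"distance_mm": 1000.0, "orientation": "floor",
                         "texture": "noise", "contrast": 0.9, "period_mm": 400.0}
                    ],
                },
            }
        ],
        "stats": {"response": "median_lateral_position_mm", "alpha": 0.05},
    }
    return config, registry
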