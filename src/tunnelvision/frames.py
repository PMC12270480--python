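"""Frame-sequence container and image-sequence I/O.

A :class:`FrameSequence` is an ordered stack of grayscale frames with
intensity in [0, 1], plus the frame rate and provenance metadata.  On disk
a sequence is a directory of zero-padded 16-bit PNGs with a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator

import imageio.v3 as iio
import numpy as np

__all__ = ["FrameSequence", "write_frame_sequence", "read_frame_sequence"]

_SIDECAR = "sequence.json"
_SCALE = 65535.0  # 16-bit quantisation keeps faint (0.01) contrast steps


@dataclass
class FrameSequence:
    """Ordered grayscale frames with intensities in [0, 1]."""

    frames: np.ndarray  # (T, H, W) float
    fps: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")
        if len(self.frames) == 0:
            raise ValueError("empty frame sequence")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of each frame."""
        return self.frames.shape[1:]


def write_frame_sequence(seq: FrameSequence, directory: str | Path) -> Path:
    """Write ``seq`` as zero-padded PNGs plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(seq.frames):
        q = np.clip(np.round(frame * _SCALE), 0, _SCALE).astype(np.uint16)
        iio.imwrite(directory / f"frame_{i:06d}.png", q)
    sidecar = {"fps": seq.fps, "n_frames": len(seq), "metadata": seq.metadata}
    (directory / _SIDECAR).write_text(json.dumps(sidecar, indent=2))
    return directory


def read_frame_sequence(directory: str | Path) -> FrameSequence:
    """Read a PNG image-sequence directory written by :func:`write_frame_sequence`."""
    directory = Path(directory)
    paths = sorted(directory.glob("frame_*.png"))
    if not paths:
        raise FileNotFoundError(f"no frames found in {directory}")
    frames = np.stack([iio.imread(p).astype(float) / _SCALE for p in paths])
    sidecar_path = directory / _SIDECAR
    fps, metadata = 30.0, {}
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        fps = sidecar.get("fps", fps)
        metadata = sidecar.get("metadata", {})
    return FrameSequence(frames=frames, fps=fps, metadata=metadata)
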