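"""Colorized point-cloud sequence I/O and region-of-interest cropping.

Frames are stored one PLY file per time step (binary little-endian on write;
ASCII and binary dialects accepted on read) with per-vertex ``x y z`` floats in
cm and ``red green blue`` uchar colors, listed by a JSON sequence manifest.
Non-finite points (depth holes) are dropped at load time.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

log = logging.getLogger(__name__)


class PointCloudIOError(RuntimeError):
    """Raised for missing files, malformed PLY headers or color-less clouds."""


@dataclass
class Frame:
    """One colorized point cloud: (N, 3) coordinates in cm plus (N, 3) uint8 RGB."""

    points: np.ndarray
    colors: np.ndarray
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points)
        self.colors = np.asarray(self.colors, dtype=np.uint8)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must have shape (N, 3)")
        if self.colors.shape != self.points.shape:
            raise ValueError("colors must match points in shape")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class FrameSequence:
    """Ordered frames at a fixed frame rate, with manifest metadata."""

    frames: list[Frame]
    frame_rate: float
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    def __iter__(self):
        return iter(self.frames)

    @property
    def duration(self) -> float:
        return len(self.frames) / self.frame_rate


@dataclass(frozen=True)
class ROIBox:
    """Axis-aligned half-open box [min, max) on each axis, in cm."""

    x: tuple[float, float]
    y: tuple[float, float]
    z: tuple[float, float]

    def __post_init__(self) -> None:
        for axis, (lo, hi) in zip("xyz", (self.x, self.y, self.z)):
            if not lo < hi:
                raise ValueError(f"ROIBox {axis} interval must satisfy min < max, got [{lo}, {hi})")

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points)
        m = np.ones(len(p), dtype=bool)
        for k, (lo, hi) in enumerate((self.x, self.y, self.z)):
            m &= (p[:, k] >= lo) & (p[:, k] < hi)
        return m


def crop(frame: Frame, box: ROIBox) -> Frame:
    """Keep exactly the points inside the half-open box, colors in correspondence."""
    m = box.contains(frame.points)
    if not m.any():
        log.warning("crop produced an empty frame (t=%.3f s)", frame.timestamp)
    return Frame(frame.points[m], frame.colors[m], frame.timestamp)


# ---------------------------------------------------------------- PLY frames

_COLOR_PROPS = ("red", "green", "blue")


def _check_ply_header(path: Path) -> None:
    """Verify the PLY header declares vertex colors; name what is missing."""
    try:
        with open(path, "rb") as fh:
            header = fh.read(4096).split(b"end_header")[0].decode("ascii", errors="replace")
    except OSError as exc:
        raise PointCloudIOError(f"cannot read PLY file {path}: {exc}") from exc
    if not header.startswith("ply"):
        raise PointCloudIOError(f"{path}: not a PLY file (missing 'ply' magic)")
    missing = [p for p in _COLOR_PROPS if f"property uchar {p}" not in header
               and f"property uint8 {p}" not in header]
    if missing:
        raise PointCloudIOError(
            f"{path}: PLY lacks vertex color propert{'ies' if len(missing) > 1 else 'y'} "
            + ", ".join(missing)
        )


def write_frame(frame: Frame, path: str | Path) -> None:
    """Write one frame as binary little-endian PLY with vertex colors."""
    pc = trimesh.PointCloud(frame.points.astype(np.float32), colors=frame.colors)
    Path(path).write_bytes(pc.export(file_type="ply"))


def read_frame(path: str | Path, timestamp: float = 0.0) -> Frame:
    path = Path(path)
    if not path.exists():
        raise PointCloudIOError(f"PLY file not found: {path}")
    _check_ply_header(path)
    try:
        cloud = trimesh.load(str(path), process=False)
    except Exception as exc:  # malformed body
        raise PointCloudIOError(f"{path}: malformed PLY: {exc}") from exc
    points = np.asarray(cloud.vertices, dtype=np.float64)
    colors = np.asarray(cloud.colors)[:, :3].astype(np.uint8)
    finite = np.isfinite(points).all(axis=1)
    dropped = int((~finite).sum())
    if dropped:
        log.info("%s: dropped %d non-finite points", path.name, dropped)
        points, colors = points[finite], colors[finite]
    return Frame(points, colors, timestamp)


# ------------------------------------------------------------- manifest I/O

def write_sequence(seq: FrameSequence, out_dir: str | Path, prefix: str = "frame") -> Path:
    """Write all frames as PLY plus a JSON manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = []
    width = max(4, len(str(len(seq) - 1)))
    for i, frame in enumerate(seq):
        name = f"{prefix}_{i:0{width}d}.ply"
        write_frame(frame, out_dir / name)
        names.append(name)
    manifest = {
        "format": "chestmorph-sequence/1",
        "units": "cm",
        "frame_rate_hz": seq.frame_rate,
        "frames": names,
        **{k: v for k, v in seq.metadata.items() if _json_safe(v)},
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except (TypeError, ValueError):
        return False


def read_sequence(manifest_path: str | Path) -> FrameSequence:
    """Load a sequence in manifest order; timestamps follow the frame rate."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise PointCloudIOError(f"manifest not found: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    try:
        rate = float(manifest["frame_rate_hz"])
        names = list(manifest["frames"])
    except KeyError as exc:
        raise PointCloudIOError(f"{manifest_path}: manifest missing key {exc}") from exc
    frames = [read_frame(manifest_path.parent / name, timestamp=i / rate)
              for i, name in enumerate(names)]
    meta = {k: v for k, v in manifest.items() if k not in ("frames",)}
    return FrameSequence(frames, rate, meta)
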