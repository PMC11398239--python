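"""Rigid alignment, channel-grid construction and depth-signal extraction.

Every frame is rigidly transformed so that (a) the table plane becomes
z = d (tilt correction; d is the camera-to-table distance), (b) the
inter-nipple line runs along the y-axis, and (c) the nipple-to-navel
direction points along +x. On the aligned cloud a 7x7 grid of 2 cm square
channels spans the nipple line to the navel and the left to the right
nipple; each channel's depth-variation signal is the ROI mean of d - z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from chestmorph.config import RunConfig
from chestmorph.io import Frame, FrameSequence, ROIBox
from chestmorph.markers import MarkerTriplet


class GeometryError(RuntimeError):
    pass


@dataclass
class RigidTransform:
    """p' = R p + t with R orthonormal, det +1."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=np.float64)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with determinant +1")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.rotation.T + self.translation

    def apply_marker_triplet(self, markers: MarkerTriplet) -> MarkerTriplet:
        from chestmorph.markers import Marker

        out = {}
        for name, m in zip(("left_nipple", "right_nipple", "navel"), markers):
            out[name] = Marker(center=self.apply(m.center[None, :])[0],
                               radius=m.radius, score=m.score)
        return MarkerTriplet(**out)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class TablePlane:
    """Fitted table plane: unit normal (camera frame), distance d, rms residual."""

    normal: np.ndarray
    d: float
    residual: float


def fit_table_plane(frame: Frame, table_region,
                    min_points: int = 100, max_residual: float = 0.5) -> TablePlane:
    """Least-squares plane through the table points inside ``table_region``.

    ``table_region`` is a single :class:`ROIBox` or a sequence of boxes whose
    union is used (a frame of strips around the patient constrains the tilt
    on both axes far better than one strip). Points far off the consensus
    plane (body parts or clutter clipped by a box) are iteratively trimmed
    at 4 robust standard deviations before the final fit. The normal is
    oriented away from the camera (positive z component) and ``d`` is the
    distance from the camera origin to the plane along it.
    """
    boxes = [table_region] if isinstance(table_region, ROIBox) else list(table_region)
    pts = np.asarray(frame.points, dtype=np.float64)
    mask = np.zeros(len(pts), dtype=bool)
    for box in boxes:
        mask |= box.contains(pts)
    pts = pts[mask]
    if len(pts) < min_points:
        raise GeometryError(f"table region holds only {len(pts)} points "
                            f"(need >= {min_points})")
    for _ in range(10):
        centroid = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
        normal = vt[-1]
        res = (pts - centroid) @ normal
        center = np.median(res)
        sigma = 1.4826 * np.median(np.abs(res - center))
        keep = np.abs(res - center) <= max(4.0 * sigma, 1e-9)
        if keep.all():
            break
        if keep.sum() < min_points:
            raise GeometryError("table region too contaminated: fewer than "
                                f"{min_points} points on the consensus plane")
        pts = pts[keep]
    if normal[2] < 0:
        normal = -normal
    d = float(normal @ centroid)
    residual = float(np.sqrt(np.mean(((pts - centroid) @ normal) ** 2)))
    if residual > max_residual:
        raise GeometryError(f"table plane residual {residual:.3f} cm exceeds "
                            f"{max_residual} cm; region likely contains non-table points")
    return TablePlane(normal=normal, d=d, residual=residual)


def compute_alignment(markers: MarkerTriplet, plane: TablePlane) -> RigidTransform:
    """Rigid transform that levels the table and puts the nipple line on y.

    After applying it: the table normal is (0, 0, 1) with table z = d, both
    nipples share the same x-coordinate, the navel lies at larger x than the
    nipples, and the mid-nipple point is at x = y = 0.
    """
    markers.check_noncollinear()
    e_z = np.asarray(plane.normal, dtype=np.float64)
    e_z = e_z / np.linalg.norm(e_z)
    ln, rn, nv = (np.asarray(m.center, dtype=np.float64) for m in markers)
    ny = rn - ln
    ny = ny - (ny @ e_z) * e_z
    n = np.linalg.norm(ny)
    if n < 1e-9:
        raise GeometryError("nipple line is parallel to the table normal")
    e_y = ny / n
    e_x = np.cross(e_y, e_z)
    mid = 0.5 * (ln + rn)
    if (nv - mid) @ e_x < 0:  # navel must end up at +x
        e_x, e_y = -e_x, -e_y
    R = np.stack([e_x, e_y, e_z])
    t = np.array([-(R @ mid)[0], -(R @ mid)[1], 0.0])
    return RigidTransform(R, t)


@dataclass
class ChannelGrid:
    """7x7 lattice of channel centers on the aligned cloud.

    ``centers[i-1, j-1]`` is the (x, y) of channel (i, j); row 1 lies on the
    nipple line, row 7 at the navel, column 1 at the left nipple. Channels
    are square ROIs of half-size ``roi_half_size`` (2 cm squares by default).
    """

    centers: np.ndarray
    roi_half_size: float = 1.0
    rows_of_interest: tuple[int, ...] = (1, 3, 5)

    @property
    def row_x(self) -> np.ndarray:
        return self.centers[:, 0, 0]

    @property
    def col_y(self) -> np.ndarray:
        return self.centers[0, :, 1]

    def center(self, i: int, j: int) -> np.ndarray:
        return self.centers[i - 1, j - 1]

    def channels_of_interest(self, central: tuple[int, int] = (4, 4)) -> list[tuple[int, int]]:
        chans = [(i, j) for i in self.rows_of_interest for j in range(1, 8)]
        if central not in chans:
            chans.append(central)
        return chans


def build_grid(markers_aligned: MarkerTriplet, roi_half_size: float = 1.0,
               rows_of_interest: tuple[int, ...] = (1, 3, 5),
               min_separation: float = 2.0) -> ChannelGrid:
    """Grid of 49 centers equidistant between the markers, on aligned coordinates."""
    ln, rn, nv = (np.asarray(m.center, dtype=np.float64) for m in markers_aligned)
    x_nip = 0.5 * (ln[0] + rn[0])
    if abs(nv[0] - x_nip) < min_separation or abs(rn[1] - ln[1]) < min_separation:
        raise GeometryError("marker span below 2 cm; channel ROIs would degenerate")
    xs = np.linspace(x_nip, nv[0], 7)
    ys = np.linspace(ln[1], rn[1], 7)
    centers = np.stack(np.meshgrid(xs, ys, indexing="ij"), axis=-1)
    return ChannelGrid(centers=centers, roi_half_size=roi_half_size,
                       rows_of_interest=tuple(rows_of_interest))


@dataclass
class DepthSignalSet:
    """Per-channel depth-variation signals r(t) at the acquisition rate.

    ``r[(i, j)]`` is the ROI mean of d - z per frame for channel (i, j);
    ``counts`` holds the per-frame point count N of each ROI. The central
    channel drives extrema detection and breath segmentation downstream.
    """

    r: dict[tuple[int, int], np.ndarray]
    counts: dict[tuple[int, int], np.ndarray]
    frame_rate: float
    d: float
    central: tuple[int, int] = (4, 4)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.r.values())))

    @property
    def central_signal(self) -> np.ndarray:
        return self.r[self.central]

    def channels(self) -> list[tuple[int, int]]:
        return list(self.r.keys())

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame({f"r_{i}_{j}": v for (i, j), v in self.r.items()})
        df.attrs["frame_rate_hz"] = self.frame_rate
        df.attrs["camera_to_table_distance_cm"] = self.d
        return df


def extract_depth_signals(sequence: FrameSequence,
                          marker_tracks: list[MarkerTriplet],
                          plane: TablePlane,
                          config: RunConfig | None = None) -> DepthSignalSet:
    """Aligned per-channel ROI means of d - z for every frame.

    The grid is rebuilt per frame from that frame's tracked markers (the
    markers ride on the breathing surface); d comes from the first frame's
    table fit and is held fixed. A channel ROI that is empty in any frame is
    an error naming the channel and frame.
    """
    config = config or RunConfig()
    if len(marker_tracks) != len(sequence):
        raise ValueError("one marker triplet per frame required")
    central = tuple(config.central_channel)
    chans: list[tuple[int, int]] | None = None
    r: dict[tuple[int, int], list[float]] = {}
    counts: dict[tuple[int, int], list[int]] = {}
    half = config.roi_half_size_cm
    for k, (frame, markers) in enumerate(zip(sequence, marker_tracks)):
        transform = compute_alignment(markers, plane)
        pts = transform.apply(frame.points)
        grid = build_grid(transform.apply_marker_triplet(markers),
                          roi_half_size=half,
                          rows_of_interest=config.rows_of_interest)
        if chans is None:
            chans = grid.channels_of_interest(central)
            r = {ch: [] for ch in chans}
            counts = {ch: [] for ch in chans}
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        row_masks = {i: np.abs(x - grid.row_x[i - 1]) <= half
                     for i in {c[0] for c in chans}}
        col_masks = {j: np.abs(y - grid.col_y[j - 1]) <= half
                     for j in {c[1] for c in chans}}
        depth = plane.d - z
        for (i, j) in chans:
            m = row_masks[i] & col_masks[j]
            n = int(m.sum())
            if n == 0:
                raise GeometryError(f"channel ({i}, {j}) has no points in frame {k}")
            r[(i, j)].append(float(depth[m].mean()))
            counts[(i, j)].append(n)
    return DepthSignalSet(r={ch: np.asarray(v) for ch, v in r.items()},
                          counts={ch: np.asarray(v) for ch, v in counts.items()},
                          frame_rate=sequence.frame_rate, d=plane.d, central=central)
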