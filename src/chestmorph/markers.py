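"""Circular fiducial detection and tracking on saturation images.

Each frame is projected to the x-y plane as a color raster (nearest-to-camera
z-buffer), converted to HSV, and the saturation channel is searched with a
circular Hough transform restricted to a window around a seed position. The
operator supplies the seed for the first frame; every following frame is
seeded with the previous frame's corrected centers, so the search area stays
narrow and detection errors do not accumulate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.feature import canny
from skimage.transform import hough_circle

from chestmorph.config import RunConfig
from chestmorph.io import Frame, FrameSequence

MARKER_NAMES = ("left_nipple", "right_nipple", "navel")


class MarkerDetectionError(RuntimeError):
    """Raised when no circle scores above threshold inside the search window."""

    def __init__(self, message: str, search_center=None, search_radius=None,
                 frame_index=None, marker_name=None):
        super().__init__(message)
        self.search_center = search_center
        self.search_radius = search_radius
        self.frame_index = frame_index
        self.marker_name = marker_name


@dataclass
class Marker:
    """One detected marker: 3-D center (cm), detected radius (cm), Hough score."""

    center: np.ndarray
    radius: float
    score: float

    @property
    def xy(self) -> np.ndarray:
        return np.asarray(self.center[:2], dtype=float)


@dataclass
class MarkerTriplet:
    left_nipple: Marker
    right_nipple: Marker
    navel: Marker

    def __iter__(self):
        return iter((self.left_nipple, self.right_nipple, self.navel))

    def __getitem__(self, name: str) -> Marker:
        return getattr(self, name)

    def centers(self) -> np.ndarray:
        return np.stack([m.center for m in self])

    def check_noncollinear(self, tol: float = 1e-3) -> None:
        a, b, c = (m.xy for m in self)
        u, v = b - a, c - a
        area2 = abs(u[0] * v[1] - u[1] * v[0])
        scale = max(np.linalg.norm(b - a), np.linalg.norm(c - a), 1.0)
        if area2 < tol * scale * scale:
            raise ValueError("marker centers are collinear")


@dataclass
class ProjectedImage:
    """Color raster of a point cloud projected along z (camera axis).

    ``colors`` is (H, W, 3) float in [0, 1], row index = x, column index = y;
    ``filled`` marks pixels that received at least one point.
    """

    colors: np.ndarray
    filled: np.ndarray
    pitch: float
    origin: tuple[float, float]

    def cm_to_px(self, xy) -> np.ndarray:
        xy = np.atleast_2d(xy)
        return (xy - np.asarray(self.origin)) / self.pitch

    def px_to_cm(self, rowcol) -> np.ndarray:
        rc = np.atleast_2d(np.asarray(rowcol, dtype=float))
        return rc * self.pitch + np.asarray(self.origin)

    @property
    def shape(self) -> tuple[int, int]:
        return self.colors.shape[:2]


def project_to_image(frame: Frame, pixel_pitch: float, fill_radius_px: int = 3) -> ProjectedImage:
    """Rasterize a frame to the x-y plane with a nearest-to-camera z-buffer.

    Empty pixels are filled by nearest neighbor within ``fill_radius_px`` so
    that sparse clouds do not leave holes that break circle voting.
    """
    if len(frame) == 0:
        raise ValueError("cannot project an empty frame")
    pts = np.asarray(frame.points, dtype=np.float64)
    x0, y0 = pts[:, 0].min(), pts[:, 1].min()
    ix = np.floor((pts[:, 0] - x0) / pixel_pitch).astype(np.intp)
    iy = np.floor((pts[:, 1] - y0) / pixel_pitch).astype(np.intp)
    H, W = int(ix.max()) + 1, int(iy.max()) + 1
    if H < 2 or W < 2:
        raise ValueError("degenerate extent: all points share x or y")
    img = np.zeros((H, W, 3), dtype=np.float32)
    filled = np.zeros((H, W), dtype=bool)
    # nearest point (smallest z) assigned last wins
    order = np.argsort(-pts[:, 2], kind="stable")
    img[ix[order], iy[order]] = frame.colors[order] / 255.0
    filled[ix, iy] = True
    if not filled.all() and fill_radius_px > 0:
        dist, (ri, ci) = ndimage.distance_transform_edt(~filled, return_indices=True)
        near = dist <= fill_radius_px
        img[near] = img[ri[near], ci[near]]
    # half-pixel offset: pixel (i, j) is centred at origin + (i+0.5)*pitch
    return ProjectedImage(img, filled, pixel_pitch,
                          (x0 + pixel_pitch / 2, y0 + pixel_pitch / 2))


def detect_marker(image: ProjectedImage, initial_center, search_radius: float,
                  radius_range: tuple[float, float],
                  score_threshold: float = 0.3) -> tuple[np.ndarray, float, float]:
    """Best Hough circle on the saturation channel near ``initial_center``.

    Returns ``(center_xy_cm, radius_cm, score)``; the center lies within
    ``search_radius`` cm of the seed. Raises :class:`MarkerDetectionError`
    when no circle scores above ``score_threshold``.
    """
    if radius_range[0] <= 0 or radius_range[1] <= radius_range[0]:
        raise ValueError("radius_range must be positive and increasing")
    seed_px = image.cm_to_px(initial_center)[0]
    H, W = image.shape
    if not (0 <= seed_px[0] < H and 0 <= seed_px[1] < W):
        raise MarkerDetectionError("initial center outside the projected image",
                                   search_center=tuple(initial_center),
                                   search_radius=search_radius)
    r_px = np.arange(max(2, int(np.floor(radius_range[0] / image.pitch))),
                     int(np.ceil(radius_range[1] / image.pitch)) + 1)
    win = int(np.ceil((search_radius + radius_range[1]) / image.pitch)) + 3
    r0, r1 = max(0, int(seed_px[0]) - win), min(H, int(seed_px[0]) + win + 1)
    c0, c1 = max(0, int(seed_px[1]) - win), min(W, int(seed_px[1]) + win + 1)
    sat = rgb2hsv(image.colors[r0:r1, c0:c1])[..., 1]
    edges = canny(sat, sigma=1.0)
    if not edges.any():
        raise MarkerDetectionError("no edges in the search window",
                                   search_center=tuple(initial_center),
                                   search_radius=search_radius)
    acc = hough_circle(edges, r_px, normalize=True, full_output=False)
    # restrict circle centers to the seed-centred search disc
    rows = np.arange(r0, r1)[:, None] - seed_px[0]
    cols = np.arange(c0, c1)[None, :] - seed_px[1]
    inside = rows ** 2 + cols ** 2 <= (search_radius / image.pitch) ** 2
    acc = np.where(inside[None, :, :], acc, -np.inf)
    k = np.unravel_index(np.argmax(acc), acc.shape)
    score = float(acc[k])
    if not np.isfinite(score) or score < score_threshold:
        raise MarkerDetectionError(
            f"no circle above score threshold {score_threshold} "
            f"(best {score if np.isfinite(score) else float('nan'):.3f})",
            search_center=tuple(initial_center), search_radius=search_radius)
    center_cm = image.px_to_cm([k[1] + r0, k[2] + c0])[0]
    return center_cm, float(r_px[k[0]] * image.pitch), score


def _refine_center_3d(frame: Frame, center_xy: np.ndarray, radius: float) -> np.ndarray:
    """3-D marker center: centroid of cloud points inside the detected circle."""
    pts = np.asarray(frame.points, dtype=np.float64)
    d2 = (pts[:, 0] - center_xy[0]) ** 2 + (pts[:, 1] - center_xy[1]) ** 2
    m = d2 <= radius ** 2
    if not m.any():
        return np.array([center_xy[0], center_xy[1], np.nan])
    return pts[m].mean(axis=0)


def detect_triplet(frame: Frame, seed: MarkerTriplet, config: RunConfig,
                   frame_index: int | None = None) -> MarkerTriplet:
    """Detect all three markers in one frame, each seeded independently."""
    image = project_to_image(frame, config.pixel_pitch_cm)
    rr = (config.marker_radius_cm * (1 - config.hough_radius_tolerance),
          config.marker_radius_cm * (1 + config.hough_radius_tolerance))
    out = {}
    for name in MARKER_NAMES:
        try:
            center_xy, radius, score = detect_marker(
                image, seed[name].xy, config.search_radius_cm, rr,
                config.hough_score_threshold)
        except MarkerDetectionError as exc:
            raise MarkerDetectionError(
                f"marker {name!r} lost"
                + (f" at frame {frame_index}" if frame_index is not None else "")
                + f": {exc}",
                search_center=exc.search_center, search_radius=exc.search_radius,
                frame_index=frame_index, marker_name=name) from exc
        center = _refine_center_3d(frame, center_xy, radius)
        out[name] = Marker(center=center, radius=radius, score=score)
    triplet = MarkerTriplet(**out)
    triplet.check_noncollinear()
    return triplet


def track_markers(sequence: FrameSequence, operator_seed: MarkerTriplet,
                  config: RunConfig | None = None) -> list[MarkerTriplet]:
    """Track the three markers across the sequence with recursive seeding.

    The operator's initial positions are corrected by detection on the first
    frame; each frame's corrected centers seed the next frame's search. A
    detection failure raises with the frame index and marker name — there is
    no silent extrapolation.
    """
    config = config or RunConfig()
    tracks: list[MarkerTriplet] = []
    seed = operator_seed
    for k, frame in enumerate(sequence):
        seed = detect_triplet(frame, seed, config, frame_index=k)
        tracks.append(seed)
    return tracks


def tracks_to_table(tracks: list[MarkerTriplet]):
    """Marker tracks as a tidy DataFrame (frame, marker, x, y, radius, score)."""
    import pandas as pd

    rows = []
    for k, tr in enumerate(tracks):
        for name in MARKER_NAMES:
            m = tr[name]
            rows.append({"frame_index": k, "marker_name": name,
                         "x_cm": m.center[0], "y_cm": m.center[1],
                         "radius_cm": m.radius, "score": m.score})
    return pd.DataFrame(rows)
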