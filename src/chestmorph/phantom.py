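"""Synthetic breathing-torso point-cloud generator with ground truth.

Emulates a supine patient on a planar table under a downward-looking depth
camera: a regular x-y lattice of points at 0.25 cm pitch, a smooth torso dome
above the table whose peak depth and breathing amplitude vary per grid row
(abdominal breathing is more pronounced than thoracic), three circular matte
markers (nipples, navel) rendered as saturated color patches, quasi-periodic
raised-cosine breathing with per-cycle period jitter, i.i.d. depth noise,
a configurable camera pose (tilt/yaw/offset), and injectable motion artifacts.

Conventions: all coordinates in cm in the camera frame; z increases away from
the camera, so the table sits at ``z = camera_to_table_distance`` and the torso
is displaced toward the camera (smaller z). The phantom's body frame (before
the pose rotation) has x running from the nipple line toward the navel and y
across the chest.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np

from chestmorph.io import Frame, FrameSequence

TABLE_COLOR = (120, 120, 120)      # neutral gray, zero saturation
SKIN_COLOR = (205, 170, 150)       # low-saturation skin tone
MARKER_COLOR = (230, 20, 20)       # fully saturated marker hue

LATTICE_PITCH_CM = 0.25            # >= 49 points per 2 cm ROI
TORSO_X_MARGIN_CM = 4.0            # dome extends this far beyond the marker span
TORSO_Y_MARGIN_CM = 4.0
PLATEAU_Y_MARGIN_CM = 1.5          # flat-top half-width beyond the nipple half-separation


class PhantomConfigError(ValueError):
    """Raised when a phantom configuration is internally inconsistent."""


@dataclass(frozen=True)
class ArtifactSpec:
    """One injected motion artifact.

    ``kind`` is one of ``step-shift`` (constant displacement toward the camera
    for the whole window), ``spike`` (half-sine pulse) or ``drift`` (linear
    ramp). ``rows``/``cols`` restrict the affected grid rows/columns
    (1-based); ``None`` means the whole torso.
    """

    onset_time: float
    duration: float
    kind: str = "step-shift"
    magnitude: float = 3.0
    rows: tuple[int, ...] | None = None
    cols: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("step-shift", "spike", "drift"):
            raise PhantomConfigError(f"unknown artifact kind {self.kind!r}")
        if self.duration <= 0 or self.onset_time < 0:
            raise PhantomConfigError("artifact window must have positive duration and onset >= 0")


@dataclass
class PhantomConfig:
    """Study conditions for one synthetic trial."""

    camera_to_table_distance: float = 53.0
    table_extent: tuple[float, float] = (36.0, 26.0)      # (x, y) lengths, cm
    # smooth dome: peak torso depth at each of the 7 grid rows (nipple line -> navel)
    torso_profile: tuple[float, ...] = (6.0, 6.2, 6.4, 6.6, 6.8, 7.0, 7.0)
    # markers on the torso surface, body-frame (x, y) in cm
    left_nipple: tuple[float, float] = (0.0, -5.0)
    right_nipple: tuple[float, float] = (0.0, 5.0)
    navel: tuple[float, float] = (14.0, 0.0)
    marker_radius: float = 1.0
    # breathing: amplitude per grid row (cm), raised-cosine cycles
    breathing_amplitude: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
    mean_period: float = 3.0
    period_jitter: float = 0.3
    amplitude_jitter: float = 0.1   # per-cycle amplitude scatter, fraction of 1
    baseline_jitter: float = 0.05   # end-expiratory level scatter, fraction of 1
    noise_sigma: float = 0.05
    # camera pose: table-plane tilt about the x and y axes, optional yaw and offset
    tilt: tuple[float, float] = (0.0, 0.0)                 # degrees
    yaw: float = 0.0                                       # degrees about z
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)   # cm
    frame_rate: float = 30.0
    duration: float = 60.0
    artifacts: tuple[ArtifactSpec, ...] = ()
    seed: int = 0

    # -- derived geometry -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return int(round(self.frame_rate * self.duration))

    @property
    def nipple_line_x(self) -> float:
        return 0.5 * (self.left_nipple[0] + self.right_nipple[0])

    @property
    def torso_center_y(self) -> float:
        return 0.5 * (self.left_nipple[1] + self.right_nipple[1])

    @property
    def nipple_half_separation(self) -> float:
        return 0.5 * abs(self.right_nipple[1] - self.left_nipple[1])

    @property
    def row_x(self) -> np.ndarray:
        """Body-frame x of the 7 grid rows (row 1 at the nipple line)."""
        return np.linspace(self.nipple_line_x, self.navel[0], 7)

    @property
    def col_y(self) -> np.ndarray:
        """Body-frame y of the 7 grid columns (column 1 at the left nipple)."""
        return np.linspace(self.left_nipple[1], self.right_nipple[1], 7)

    def validate(self) -> None:
        if self.marker_radius <= 0:
            raise PhantomConfigError("marker_radius must be positive")
        if self.frame_rate <= 0 or self.duration <= 0:
            raise PhantomConfigError("frame_rate and duration must be positive")
        if len(self.torso_profile) != 7 or len(self.breathing_amplitude) != 7:
            raise PhantomConfigError("torso_profile and breathing_amplitude need 7 per-row values")
        if min(self.breathing_amplitude) < 0:
            raise PhantomConfigError("breathing amplitudes must be >= 0")
        if min(self.torso_profile) <= max(self.breathing_amplitude) * 0.0 or min(self.torso_profile) <= 0:
            raise PhantomConfigError("torso peak depths must be positive")
        if self.mean_period <= 0 or self.period_jitter < 0 or self.period_jitter >= self.mean_period:
            raise PhantomConfigError("need 0 <= period_jitter < mean_period and mean_period > 0")
        if self.noise_sigma < 0:
            raise PhantomConfigError("noise_sigma must be >= 0")
        if not 0 <= self.amplitude_jitter < 1:
            raise PhantomConfigError("amplitude_jitter must be in [0, 1)")
        if not 0 <= self.baseline_jitter < 1:
            raise PhantomConfigError("baseline_jitter must be in [0, 1)")
        a = np.array([*self.left_nipple, 0.0])
        b = np.array([*self.right_nipple, 0.0])
        c = np.array([*self.navel, 0.0])
        area2 = np.linalg.norm(np.cross(b - a, c - a))
        scale = max(np.linalg.norm(b - a), np.linalg.norm(c - a), 1.0)
        if area2 < 1e-6 * scale * scale:
            raise PhantomConfigError("marker positions are collinear")
        for spec in self.artifacts:
            if spec.onset_time + spec.duration > self.duration + 1e-9:
                raise PhantomConfigError("artifact window extends past the sequence duration")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["artifacts"] = [dataclasses.asdict(s) for s in self.artifacts]
        return d


@dataclass
class GroundTruth:
    """Per-frame truth for pipeline validation.

    ``marker_centers`` are camera-frame (x, y, z) per frame for (left nipple,
    right nipple, navel). ``r`` holds the clean (noise- and artifact-free)
    per-channel depth-variation signals obtained by averaging the analytic
    surface over each 2 cm ROI; artifacts appear only in ``artifact_masks``.
    """

    marker_centers: np.ndarray                      # (n_frames, 3, 3)
    r: dict[tuple[int, int], np.ndarray]            # channel -> (n_frames,)
    minima_indices: np.ndarray
    maxima_indices: np.ndarray
    cycle_periods: np.ndarray                       # per complete cycle, s
    cycle_gains: np.ndarray                         # per-cycle amplitude factor
    cycle_offsets: np.ndarray                       # end-expiratory level per cycle start
    artifact_masks: dict[tuple[int, int], np.ndarray]
    merged_artifact_mask: np.ndarray
    config: PhantomConfig

    def n_frames(self) -> int:
        return self.marker_centers.shape[0]


# --------------------------------------------------------------- waveform

def _breathing_cycles(config: PhantomConfig, rng: np.random.Generator):
    """Cycle start times, periods, amplitude factors and end-expiratory offsets.

    Offsets has one extra entry (the level at the end of the last cycle) so
    the baseline can be interpolated across every cycle.
    """
    starts, periods, gains, t = [], [], [], 0.0
    while t < config.duration:
        T = config.mean_period + rng.uniform(-config.period_jitter, config.period_jitter) \
            if config.period_jitter > 0 else config.mean_period
        g = 1.0 + rng.uniform(-config.amplitude_jitter, config.amplitude_jitter) \
            if config.amplitude_jitter > 0 else 1.0
        starts.append(t)
        periods.append(T)
        gains.append(g)
        t += T
    if config.baseline_jitter > 0:
        offsets = rng.uniform(-config.baseline_jitter, config.baseline_jitter,
                              size=len(starts) + 1)
    else:
        offsets = np.zeros(len(starts) + 1)
    return np.array(starts), np.array(periods), np.array(gains), offsets


def _breathing_signal(t: np.ndarray, starts: np.ndarray, periods: np.ndarray,
                      gains: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Raised-cosine breathing drive with a slowly varying end-expiratory level.

    The baseline is cosine-eased between the per-cycle-start offsets, so its
    slope vanishes at the cycle boundaries and the signal minima stay exactly
    at the cycle starts (the raised-cosine curvature dominates there).
    """
    k = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(starts) - 1)
    u = np.clip((t - starts[k]) / periods[k], 0.0, 1.0)
    baseline = offsets[k] + (offsets[k + 1] - offsets[k]) * (0.5 - 0.5 * np.cos(np.pi * u))
    return gains[k] * (0.5 - 0.5 * np.cos(2.0 * np.pi * u)) + baseline


def _pose_matrix(config: PhantomConfig) -> np.ndarray:
    rx, ry = np.deg2rad(config.tilt)
    rz = np.deg2rad(config.yaw)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


class _Surface:
    """Analytic torso surface over the body-frame lattice."""

    def __init__(self, config: PhantomConfig):
        c = config
        self.xc, self.yc = c.nipple_line_x, c.torso_center_y
        half_sep = c.nipple_half_separation
        self.y_plateau = half_sep + PLATEAU_Y_MARGIN_CM
        self.y_half = half_sep + TORSO_Y_MARGIN_CM
        rows = c.row_x
        self.x_lo = rows[0] - TORSO_X_MARGIN_CM
        self.x_hi = rows[-1] + TORSO_X_MARGIN_CM
        self.knots_x = np.concatenate(([self.x_lo], rows, [self.x_hi]))
        self.knots_P = np.concatenate(([0.0], c.torso_profile, [0.0]))
        self.knots_A = np.concatenate(([0.0], c.breathing_amplitude, [0.0]))

    def lateral_weight(self, y: np.ndarray) -> np.ndarray:
        u = np.abs(np.asarray(y, dtype=float) - self.yc)
        w = np.zeros_like(u)
        w[u <= self.y_plateau] = 1.0
        taper = (u > self.y_plateau) & (u < self.y_half)
        w[taper] = 0.5 + 0.5 * np.cos(np.pi * (u[taper] - self.y_plateau)
                                      / (self.y_half - self.y_plateau))
        return w

    def base_and_amp(self, x: np.ndarray, y: np.ndarray):
        """Static depth P(x)w(y) and breathing amplitude A(x)w(y) per point."""
        w = self.lateral_weight(y)
        inside = (x >= self.x_lo) & (x <= self.x_hi)
        P = np.where(inside, np.interp(x, self.knots_x, self.knots_P), 0.0) * w
        A = np.where(inside, np.interp(x, self.knots_x, self.knots_A), 0.0) * w
        return P, A


def _channel_centers(config: PhantomConfig, channels) -> dict[tuple[int, int], tuple[float, float]]:
    rows, cols = config.row_x, config.col_y
    return {(i, j): (rows[i - 1], cols[j - 1]) for (i, j) in channels}


def default_channels(config: PhantomConfig,
                     rows_of_interest=(1, 3, 5),
                     central=(4, 4)) -> list[tuple[int, int]]:
    chans = [(i, j) for i in rows_of_interest for j in range(1, 8)]
    if central not in chans:
        chans.append(central)
    return chans


# ------------------------------------------------------------- artifacts

def _artifact_shape(kind: str, rel: np.ndarray) -> np.ndarray:
    """Displacement profile over the window, rel in [0, 1)."""
    if kind == "step-shift":
        return np.ones_like(rel)
    if kind == "spike":
        return np.sin(np.pi * rel)
    return rel  # drift


def _spec_window(spec: ArtifactSpec, frame_rate: float, n_frames: int) -> tuple[int, int]:
    on = int(round(spec.onset_time * frame_rate))
    n = int(round(spec.duration * frame_rate))
    return on, min(on + n, n_frames)


def _spec_region_mask(spec: ArtifactSpec, config: PhantomConfig,
                      x: np.ndarray, y: np.ndarray, torso: np.ndarray) -> np.ndarray:
    """Body-frame point mask for the affected region."""
    m = torso.copy()
    if spec.rows is not None:
        rows = config.row_x
        half = 0.5 * (rows[1] - rows[0])
        band = np.zeros_like(m)
        for i in spec.rows:
            band |= np.abs(x - rows[i - 1]) <= half
        m &= band
    if spec.cols is not None:
        cols = config.col_y
        half = 0.5 * abs(cols[1] - cols[0])
        band = np.zeros_like(m)
        for j in spec.cols:
            band |= np.abs(y - cols[j - 1]) <= half
        m &= band
    return m


def _spec_channel_mask(spec: ArtifactSpec, channel: tuple[int, int]) -> bool:
    i, j = channel
    return (spec.rows is None or i in spec.rows) and (spec.cols is None or j in spec.cols)


def _warn_on_overlap(specs) -> None:
    for a in range(len(specs)):
        for b in range(a + 1, len(specs)):
            sa, sb = specs[a], specs[b]
            t_overlap = (sa.onset_time < sb.onset_time + sb.duration
                         and sb.onset_time < sa.onset_time + sa.duration)
            rows_overlap = sa.rows is None or sb.rows is None or set(sa.rows) & set(sb.rows)
            cols_overlap = sa.cols is None or sb.cols is None or set(sa.cols) & set(sb.cols)
            if t_overlap and rows_overlap and cols_overlap:
                warnings.warn("overlapping artifact specs on the same region; "
                              "displacements are summed", stacklevel=3)


def artifact_masks(specs, config: PhantomConfig,
                   channels=None) -> tuple[dict[tuple[int, int], np.ndarray], np.ndarray]:
    """Per-channel boolean sample masks marking artifact-contaminated samples."""
    channels = channels if channels is not None else default_channels(config)
    n = config.n_frames
    masks = {ch: np.zeros(n, dtype=bool) for ch in channels}
    for spec in specs:
        lo, hi = _spec_window(spec, config.frame_rate, n)
        for ch in channels:
            if _spec_channel_mask(spec, ch):
                masks[ch][lo:hi] = True
    merged = np.zeros(n, dtype=bool)
    for m in masks.values():
        merged |= m
    return masks, merged


def inject_artifacts(sequence: FrameSequence, specs, config: PhantomConfig,
                     channels=None):
    """Displace frames inside each artifact window; returns (sequence, masks).

    The displacement is applied along the body-frame z-axis (toward the
    camera) to the points of the affected region; the frames are modified in
    place. Overlapping specs on the same region are summed with a warning.
    """
    specs = list(specs)
    for spec in specs:
        if spec.onset_time + spec.duration > sequence.duration + 1e-9:
            raise PhantomConfigError("artifact window extends past the sequence duration")
    _warn_on_overlap(specs)
    surface = _Surface(config)
    R = _pose_matrix(config)
    t_off = np.asarray(config.offset)
    e_z_cam = R @ np.array([0.0, 0.0, 1.0])
    n = len(sequence)
    for spec in specs:
        lo, hi = _spec_window(spec, config.frame_rate, n)
        rel = (np.arange(lo, hi) - lo) / max(hi - lo, 1)
        disp = spec.magnitude * _artifact_shape(spec.kind, rel)
        for k, fi in enumerate(range(lo, hi)):
            frame = sequence[fi]
            body = (frame.points.astype(np.float64) - t_off) @ R  # R^T applied row-wise
            P, _ = surface.base_and_amp(body[:, 0], body[:, 1])
            torso = P > 1e-9
            m = _spec_region_mask(spec, config, body[:, 0], body[:, 1], torso)
            pts = frame.points.astype(np.float64)
            pts[m] -= disp[k] * e_z_cam
            frame.points = pts.astype(frame.points.dtype)
    masks, merged = artifact_masks(specs, config, channels)
    return sequence, (masks, merged)


# ------------------------------------------------------------- generation

def generate_sequence(config: PhantomConfig,
                      channels=None) -> tuple[FrameSequence, GroundTruth]:
    """Render the phantom trial; identical config and seed give identical output."""
    config.validate()
    channels = channels if channels is not None else default_channels(config)
    rng = np.random.default_rng(config.seed)
    surface = _Surface(config)

    # static body-frame lattice centred on the torso; offset by half a pitch
    # so no lattice point sits exactly on a 2 cm channel-ROI boundary (a real
    # sensor never samples exactly on an analysis edge, and an edge-aligned
    # lattice makes ROI means knife-edge sensitive to numerical jitter)
    ext_x, ext_y = config.table_extent
    half_pitch = 0.5 * LATTICE_PITCH_CM
    cx = 0.5 * (surface.x_lo + surface.x_hi)
    xs = np.arange(cx - ext_x / 2 + half_pitch, cx + ext_x / 2 + 1e-9, LATTICE_PITCH_CM)
    ys = np.arange(surface.yc - ext_y / 2 + half_pitch, surface.yc + ext_y / 2 + 1e-9,
                   LATTICE_PITCH_CM)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    x, y = X.ravel(), Y.ravel()
    P, A = surface.base_and_amp(x, y)
    torso = P > 1e-9

    # colors: static per lattice point
    colors = np.tile(np.array(TABLE_COLOR, dtype=np.uint8), (len(x), 1))
    colors[torso] = SKIN_COLOR
    for mx, my in (config.left_nipple, config.right_nipple, config.navel):
        patch = (x - mx) ** 2 + (y - my) ** 2 <= config.marker_radius ** 2
        colors[patch & torso] = MARKER_COLOR

    starts, periods, gains, offsets = _breathing_cycles(config, rng)
    n = config.n_frames
    t = np.arange(n) / config.frame_rate
    s = _breathing_signal(t, starts, periods, gains, offsets)

    d = config.camera_to_table_distance
    R = _pose_matrix(config)
    posed = not (np.allclose(R, np.eye(3)) and config.offset == (0.0, 0.0, 0.0))
    t_off = np.asarray(config.offset, dtype=float)

    # marker ground truth (on the surface, breathing with it)
    m_xy = np.array([config.left_nipple, config.right_nipple, config.navel])
    mP, mA = surface.base_and_amp(m_xy[:, 0], m_xy[:, 1])
    marker_centers = np.empty((n, 3, 3))
    frames = []
    for k in range(n):
        z = d - (P + A * s[k])
        if config.noise_sigma > 0:
            z = z + rng.normal(0.0, config.noise_sigma, size=z.shape)
        pts = np.column_stack((x, y, z))
        mk = np.column_stack((m_xy, d - (mP + mA * s[k])))
        if posed:
            pts = pts @ R.T + t_off
            mk = mk @ R.T + t_off
        marker_centers[k] = mk
        frames.append(Frame(pts.astype(np.float32), colors, timestamp=k / config.frame_rate))

    seq = FrameSequence(frames, config.frame_rate,
                        metadata={"phantom": True, "seed": config.seed,
                                  "config": config.to_dict()})

    # clean per-channel ROI-mean signals from the analytic surface
    centers = _channel_centers(config, channels)
    r = {}
    for ch, (cxx, cyy) in centers.items():
        roi = (np.abs(x - cxx) <= 1.0) & (np.abs(y - cyy) <= 1.0)
        r[ch] = P[roi].mean() + A[roi].mean() * s

    # true extrema sample indices (interior only)
    minima = np.round(starts * config.frame_rate).astype(int)
    minima = minima[(minima > 0) & (minima < n - 1)]
    max_t = starts + periods / 2.0
    maxima = np.round(max_t * config.frame_rate).astype(int)
    maxima = maxima[(maxima > 0) & (maxima < n - 1)]

    if config.artifacts:
        seq, (masks, merged) = inject_artifacts(seq, config.artifacts, config, channels)
    else:
        masks = {ch: np.zeros(n, dtype=bool) for ch in channels}
        merged = np.zeros(n, dtype=bool)

    gt = GroundTruth(marker_centers=marker_centers, r=r,
                     minima_indices=minima, maxima_indices=maxima,
                     cycle_periods=periods[:-1] if len(periods) > 1 else periods,
                     cycle_gains=gains[:-1] if len(gains) > 1 else gains,
                     cycle_offsets=offsets,
                     artifact_masks=masks, merged_artifact_mask=merged,
                     config=config)
    return seq, gt


# ---------------------------------------------------------------- helpers

def table_roi_box(config: PhantomConfig):
    """Camera-frame table-only region (a frame of strips around the torso).

    Returns a list of :class:`~chestmorph.io.ROIBox` covering the table
    margins on all four sides of the torso, so the plane fit is constrained
    on both tilt axes. Raises when the table extent leaves no margin.
    """
    from chestmorph.io import ROIBox

    surface = _Surface(config)
    ext_x, ext_y = config.table_extent
    cx = 0.5 * (surface.x_lo + surface.x_hi)
    x_min, x_max = cx - ext_x / 2 + 0.25, cx + ext_x / 2 - 0.25
    y_min, y_max = surface.yc - ext_y / 2 + 0.25, surface.yc + ext_y / 2 - 0.25
    d = config.camera_to_table_distance
    R = _pose_matrix(config)
    off = np.asarray(config.offset)

    def strip(x0, x1, y0, y1):
        if x1 - x0 < 1.0 or y1 - y0 < 1.0:
            return None
        corners = np.array([[xx, yy, zz]
                            for xx in (x0, x1) for yy in (y0, y1)
                            for zz in (d - 0.5, d + 0.5)])
        posed = corners @ R.T + off
        lo, hi = posed.min(axis=0), posed.max(axis=0)
        lo += np.array([0.3, 0.3, -1.0])   # shrink x/y, widen z
        hi += np.array([-0.3, -0.3, 1.0])
        if hi[0] - lo[0] < 0.5 or hi[1] - lo[1] < 0.5:
            return None
        return ROIBox(x=(lo[0], hi[0]), y=(lo[1], hi[1]), z=(lo[2], hi[2]))

    yb0, yb1 = surface.yc - surface.y_half - 1.0, surface.yc + surface.y_half + 1.0
    xb0, xb1 = surface.x_lo - 1.0, surface.x_hi + 1.0
    strips = [
        strip(x_min, x_max, y_min, yb0),   # below the torso
        strip(x_min, x_max, yb1, y_max),   # above the torso
        strip(x_min, xb0, y_min, y_max),   # left of the torso
        strip(xb1, x_max, y_min, y_max),   # right of the torso
    ]
    strips = [s for s in strips if s is not None]
    if not strips:
        raise PhantomConfigError("table extent leaves no torso-free margin for plane fitting")
    return strips


def true_marker_tracks(gt: GroundTruth) -> list:
    """Per-frame MarkerTriplets from the ground truth (bypasses detection)."""
    from chestmorph.markers import Marker, MarkerTriplet

    tracks = []
    for k in range(gt.n_frames()):
        c = gt.marker_centers[k]
        tracks.append(MarkerTriplet(
            left_nipple=Marker(center=c[0].copy(), radius=gt.config.marker_radius, score=1.0),
            right_nipple=Marker(center=c[1].copy(), radius=gt.config.marker_radius, score=1.0),
            navel=Marker(center=c[2].copy(), radius=gt.config.marker_radius, score=1.0)))
    return tracks


def operator_seed(gt: GroundTruth, offset=(0.3, -0.3)):
    """An imperfect operator click: first-frame true centers plus an offset."""
    from chestmorph.markers import Marker, MarkerTriplet

    c = gt.marker_centers[0]
    dx, dy = offset
    mk = [Marker(center=np.array([c[i, 0] + dx, c[i, 1] + dy, c[i, 2]]),
                 radius=gt.config.marker_radius, score=0.0) for i in range(3)]
    return MarkerTriplet(left_nipple=mk[0], right_nipple=mk[1], navel=mk[2])
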