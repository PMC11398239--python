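"""Breath segmentation and cleaning of depth-variation signals.

The central channel's signal is low-pass filtered (4th-order Butterworth,
1 Hz cutoff, applied forward-backward so extrema do not shift), local extrema
are detected and repaired to a strict min-max-min alternation, and each
segment between consecutive minima becomes one breath. The same central
indices segment every other channel, so all channels always carry the same
number of breaths.

Artifacts (patient movements, sensor dropouts) are found with a continuous
wavelet transform: the scalogram of each raw channel is summed across scales
into a 1-D power criterion, the top percentile of which marks artifact
samples; breaths overlapping the union of all channels' marks are dropped.
Finally, breaths are gated on (period, amplitude) features against Gaussian
models of the session(s): a breath is kept only if its membership probability
is at least the floor (5%) under every model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.stats import chi2

from chestmorph.config import RunConfig
from chestmorph.geometry import DepthSignalSet

# Morlet-style analyzing wavelet psi(t) = exp(-t^2) cos(pi*sqrt(2/ln 2)*t):
# a Gaussian envelope whose oscillation frequency makes the half-power width
# of the frequency response one octave.
_OMEGA0 = np.pi * np.sqrt(2.0 / np.log(2.0))
#: oscillation frequency of the wavelet in cycles per unit time
WAVELET_CENTER_FREQUENCY = _OMEGA0 / (2.0 * np.pi)


class RespirationError(RuntimeError):
    pass


# ------------------------------------------------------------- filtering

def smooth(x: np.ndarray, frame_rate: float, cutoff_hz: float = 1.0,
           order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass; same length as the input."""
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 30:
        raise RespirationError(f"signal too short to filter ({len(x)} samples)")
    sos = sps.butter(order, cutoff_hz, fs=frame_rate, output="sos")
    return sps.sosfiltfilt(sos, x)


# ---------------------------------------------------------------- extrema

def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Interior local maxima; a plateau contributes its leftmost sample."""
    d = np.diff(x)
    s = np.sign(d)
    nz = np.nonzero(s)[0]
    if len(nz) == 0:
        return np.array([], dtype=int)
    # carry the next nonzero slope backwards across flat runs, so a plateau
    # peak registers at its leftmost sample
    filled = s.copy()
    nxt = np.full(len(s) + 1, len(s))
    for i in range(len(s) - 1, -1, -1):
        nxt[i] = i if s[i] != 0 else nxt[i + 1]
    valid = nxt[:-1] < len(s)
    filled[valid] = s[nxt[:-1][valid]]
    rise_fall = (filled[:-1] > 0) & (filled[1:] < 0)
    return np.nonzero(rise_fall)[0] + 1


def _repair_alternation(x: np.ndarray, minima: np.ndarray,
                        maxima: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse runs of same-type extrema, keeping the most extreme sample."""
    events = sorted([(i, "min") for i in minima] + [(i, "max") for i in maxima])
    out: list[tuple[int, str]] = []
    for idx, kind in events:
        if out and out[-1][1] == kind:
            prev = out[-1][0]
            better = (x[idx] > x[prev]) if kind == "max" else (x[idx] < x[prev])
            if better:
                out[-1] = (idx, kind)
        else:
            out.append((idx, kind))
    new_min = np.array([i for i, k in out if k == "min"], dtype=int)
    new_max = np.array([i for i, k in out if k == "max"], dtype=int)
    return new_min, new_max


def detect_extrema(smoothed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(minima, maxima) indices of the smoothed signal, strictly alternating.

    Endpoints are never extrema; plateaus resolve to their leftmost sample;
    consecutive same-type extrema are merged to the more extreme one.
    """
    x = np.asarray(smoothed, dtype=np.float64)
    maxima = _local_maxima(x)
    minima = _local_maxima(-x)
    minima, maxima = _repair_alternation(x, minima, maxima)
    if len(minima) < 2:
        warnings.warn("fewer than 2 minima: zero breaths detected", stacklevel=2)
    return minima, maxima


# ----------------------------------------------------------------- breaths

@dataclass(frozen=True)
class BreathSegment:
    """One breath: the span between two consecutive central-channel minima."""

    breath_id: int
    start_min_index: int
    max_index: int
    end_min_index: int
    period: float      # s
    amplitude: float   # cm, r(max) - mean of r at the two bounding minima

    def __post_init__(self) -> None:
        if not self.start_min_index < self.max_index < self.end_min_index:
            raise ValueError("breath indices must satisfy start < max < end")


def separate_breaths(smoothed_central: np.ndarray, minima: np.ndarray,
                     maxima: np.ndarray, frame_rate: float) -> list[BreathSegment]:
    """One breath per consecutive minima pair on the central channel.

    The returned index triples are shared by every channel, which guarantees
    an identical breath count on all channels.
    """
    x = np.asarray(smoothed_central, dtype=np.float64)
    breaths = []
    for b, (lo, hi) in enumerate(zip(minima[:-1], minima[1:])):
        between = maxima[(maxima > lo) & (maxima < hi)]
        if len(between) == 0:
            continue  # alternation repair should prevent this
        m = int(between[np.argmax(x[between])])
        amp = x[m] - 0.5 * (x[lo] + x[hi])
        breaths.append(BreathSegment(breath_id=b, start_min_index=int(lo),
                                     max_index=m, end_min_index=int(hi),
                                     period=(hi - lo) / frame_rate,
                                     amplitude=float(amp)))
    return breaths


# -------------------------------------------------------------------- CWT

@dataclass
class Scalogram:
    """|W(a, b)| magnitudes, shape (n_scales, n_samples)."""

    magnitude: np.ndarray
    scales: np.ndarray  # in samples

    def criterion(self) -> np.ndarray:
        """1-D power profile: scalogram summed across scales."""
        return self.magnitude.sum(axis=0)


def wavelet(t: np.ndarray) -> np.ndarray:
    """The analyzing wavelet evaluated at time t (psi(0) = 1)."""
    t = np.asarray(t, dtype=np.float64)
    return np.exp(-t * t) * np.cos(_OMEGA0 * t)


def scales_for_band(frame_rate: float, n_scales: int = 64,
                    f_min: float = 0.05, f_max: float = 5.0) -> np.ndarray:
    """Log-spaced scales (in samples) whose pseudo-frequencies span [f_min, f_max]."""
    freqs = np.geomspace(f_min, f_max, n_scales)
    return WAVELET_CENTER_FREQUENCY * frame_rate / freqs


def scale_to_frequency(scales: np.ndarray, frame_rate: float) -> np.ndarray:
    """Pseudo-frequency (Hz) of each scale (in samples)."""
    return WAVELET_CENTER_FREQUENCY * frame_rate / np.asarray(scales)


def compute_scalogram(x: np.ndarray, scales: np.ndarray) -> Scalogram:
    """CWT magnitudes with 1/sqrt(a) normalization (equal energy per scale).

    The signal is reflect-padded before convolution so boundary roll-off does
    not masquerade as an artifact.
    """
    x = np.asarray(x, dtype=np.float64)
    scales = np.atleast_1d(np.asarray(scales, dtype=np.float64))
    if np.any(scales <= 0):
        raise ValueError("scales must be positive")
    if len(x) == 0:
        raise ValueError("empty signal")
    support = int(np.ceil(4.0 * scales.max()))
    pad = min(support, len(x) - 1) if len(x) > 1 else 0
    xp = np.pad(x, pad, mode="reflect") if pad else x
    W = np.empty((len(scales), len(x)))
    for k, a in enumerate(scales):
        L = int(np.ceil(4.0 * a))
        tt = np.arange(-L, L + 1) / a
        psi = wavelet(tt) / np.sqrt(a)
        w = sps.fftconvolve(xp, psi, mode="same")  # psi is even: conv == corr
        W[k] = np.abs(w[pad:pad + len(x)] if pad else w)
    return Scalogram(magnitude=W, scales=scales)


# ------------------------------------------------------- artifact removal

def detect_artifact_samples(signals: DepthSignalSet | dict,
                            config: RunConfig | None = None):
    """Per-channel artifact sample masks and their union.

    For each channel the criterion is the scalogram of the raw (unsmoothed,
    mean-removed) signal summed across scales; samples whose criterion
    exceeds its 99th percentile are flagged. The merged mask is the union
    over channels — an artifact seen anywhere contaminates that time span
    for all channels — dilated by the detector's time localization tolerance
    (1 s): the percentile rule marks only the crest of the wavelet response,
    which for a sustained event (e.g. a step shift) can sit well inside the
    event while its flanks stay below the threshold, so the span an event
    contaminates extends about one breathing-band time constant beyond the
    flagged crest on each side. Per-channel masks are the raw threshold
    exceedances (exactly the top percentile).
    """
    config = config or RunConfig()
    if isinstance(signals, DepthSignalSet):
        channel_signals = signals.r
        fs = signals.frame_rate
    else:
        channel_signals, fs = dict(signals), 30.0
    scales = scales_for_band(fs, config.cwt_n_scales,
                             config.cwt_freq_min_hz, config.cwt_freq_max_hz)
    masks = {}
    merged = None
    for ch, x in channel_signals.items():
        crit = compute_scalogram(np.asarray(x) - np.mean(x), scales).criterion()
        thr = np.percentile(crit, config.artifact_percentile)
        m = crit > thr
        masks[ch] = m
        merged = m.copy() if merged is None else (merged | m)
    half = int(round(config.artifact_dilation_s * fs))
    if half > 0 and merged is not None and merged.any():
        kernel = np.ones(2 * half + 1)
        merged = np.convolve(merged.astype(float), kernel, mode="same") > 0
    return masks, merged


def remove_artifact_breaths(breaths: list[BreathSegment],
                            merged_mask: np.ndarray) -> tuple[list[BreathSegment], list[BreathSegment]]:
    """Drop every breath whose span touches a flagged sample.

    Returns (retained, removed). All channels share these segments, so the
    retained count is identical everywhere. Raises if nothing survives.
    """
    merged_mask = np.asarray(merged_mask, dtype=bool)
    retained, removed = [], []
    for b in breaths:
        if merged_mask[b.start_min_index:b.end_min_index + 1].any():
            removed.append(b)
        else:
            retained.append(b)
    if breaths and not retained:
        raise RespirationError("no clean breathing detected: every breath "
                               "overlaps an artifact")
    return retained, removed


# ----------------------------------------------------------------- gating

def breath_features(breaths: list[BreathSegment]) -> np.ndarray:
    """(n, 2) array of (period_s, amplitude_cm)."""
    return np.array([[b.period, b.amplitude] for b in breaths], dtype=np.float64).reshape(-1, 2)


@dataclass
class BreathFeatureModel:
    """Gaussian model of a session's breath features (period, amplitude)."""

    mean: np.ndarray
    covariance: np.ndarray

    @classmethod
    def fit(cls, features: np.ndarray) -> "BreathFeatureModel":
        f = np.asarray(features, dtype=np.float64)
        if f.ndim != 2 or len(f) < 5:
            raise RespirationError("need at least 5 breaths to estimate the "
                                   "feature covariance")
        cov = np.cov(f, rowvar=False, ddof=1)
        eig = np.linalg.eigvalsh(cov)
        floor_eig = 1e-12 * max(eig.max(), 1.0)
        if eig.min() <= floor_eig:
            # near-identical breaths (e.g. a deterministic recording): a tiny
            # ridge keeps the model usable; such breaths all sit at zero
            # Mahalanobis distance and are kept by the gate
            cov = cov + floor_eig * np.eye(cov.shape[0])
        return cls(mean=f.mean(axis=0), covariance=cov)

    def membership(self, features: np.ndarray) -> np.ndarray:
        """Probability mass outside the point's density contour: chi2 tail of
        the squared Mahalanobis distance."""
        f = np.atleast_2d(np.asarray(features, dtype=np.float64))
        diff = f - self.mean
        d2 = np.einsum("ij,jk,ik->i", diff, np.linalg.inv(self.covariance), diff)
        return chi2.sf(d2, df=f.shape[1])


def gate_breaths(features_a: np.ndarray, features_b: np.ndarray | None = None,
                 floor: float = 0.05):
    """Keep breaths inside the >= floor membership region of both sessions.

    Returns ``(keep_a, keep_b, (model_a, model_b))`` boolean masks. With a
    single session the gate degenerates to self-gating against the session's
    own model (``keep_b`` and ``model_b`` are None).
    """
    model_a = BreathFeatureModel.fit(features_a)
    if features_b is None:
        return model_a.membership(features_a) >= floor, None, (model_a, None)
    model_b = BreathFeatureModel.fit(features_b)
    keep_a = (model_a.membership(features_a) >= floor) & \
             (model_b.membership(features_a) >= floor)
    keep_b = (model_a.membership(features_b) >= floor) & \
             (model_b.membership(features_b) >= floor)
    return keep_a, keep_b, (model_a, model_b)
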