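"""Run configuration for the processing pipeline.

All tunables of the processing chain with their defaults. Values that come from
the measurement protocol (2 cm ROIs, 1 Hz/4th-order low-pass, 99th-percentile
artifact criterion, 5% membership floor, 1.5 IQR fence) default to the
protocol's values; purely numerical knobs (pixel pitch, search radius, wavelet
scale range) are package choices documented in docs/methods.md.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class RunConfig:
    # marker tracking
    pixel_pitch_cm: float = 0.1          # cm per pixel of the x-y projection
    search_radius_cm: float = 2.0        # seed-centred search window for Hough detection
    marker_radius_cm: float = 1.0        # nominal fiducial radius
    hough_radius_tolerance: float = 0.5  # radius range = nominal * (1 +/- tol)
    hough_score_threshold: float = 0.3   # min normalized accumulator peak
    # geometry
    roi_half_size_cm: float = 1.0        # channels are 2 cm squares
    rows_of_interest: tuple[int, ...] = (1, 3, 5)
    central_channel: tuple[int, int] = (4, 4)
    min_table_points: int = 100
    max_plane_residual_cm: float = 0.5
    # respiration
    filter_order: int = 4
    filter_cutoff_hz: float = 1.0
    cwt_n_scales: int = 64
    cwt_freq_min_hz: float = 0.05
    cwt_freq_max_hz: float = 5.0
    artifact_percentile: float = 99.0
    artifact_dilation_s: float = 1.0     # merged-mask dilation: detector's
    #                                      time localization tolerance
    membership_floor: float = 0.05
    # cross sections
    iqr_factor: float = 1.5
    # misc
    seed: int = 0

    def validate(self) -> None:
        if self.pixel_pitch_cm <= 0:
            raise ValueError("pixel_pitch_cm must be positive")
        if self.roi_half_size_cm <= 0:
            raise ValueError("roi_half_size_cm must be positive")
        if not (0 < self.artifact_percentile < 100):
            raise ValueError("artifact_percentile must be in (0, 100)")
        if self.artifact_dilation_s < 0:
            raise ValueError("artifact_dilation_s must be non-negative")
        if not (0 <= self.membership_floor <= 1):
            raise ValueError("membership_floor must be in [0, 1]")
        if self.cwt_freq_min_hz <= 0 or self.cwt_freq_max_hz <= self.cwt_freq_min_hz:
            raise ValueError("wavelet frequency band must satisfy 0 < fmin < fmax")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rows_of_interest"] = list(self.rows_of_interest)
        d["central_channel"] = list(self.central_channel)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        kw = {k: v for k, v in d.items() if k in known}
        if "rows_of_interest" in kw:
            kw["rows_of_interest"] = tuple(kw["rows_of_interest"])
        if "central_channel" in kw:
            kw["central_channel"] = tuple(kw["central_channel"])
        return cls(**kw)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
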