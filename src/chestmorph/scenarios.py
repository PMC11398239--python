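"""Validation scenarios: fixed study conditions for end-to-end checks.

Each function returns :class:`~chestmorph.phantom.PhantomConfig` objects for a
scenario with a known closed-form ground truth (configured amplitude, cycle
count, area-change percentage, ...). The conditions are design choices fixed
up front — e.g. the metric-recovery pair keeps the per-cycle jitters moderate
so that the sampling error of the medoid representative stays well below the
tolerance against which the recovered metric is judged — and are shared by the
test suite and the acceptance script so both validate the same experiment.
"""

from __future__ import annotations

import numpy as np

from chestmorph.config import RunConfig
from chestmorph.phantom import (
    ArtifactSpec,
    PhantomConfig,
    generate_sequence,
    table_roi_box,
    true_marker_tracks,
)
from chestmorph.pipeline import SessionResult, process_sequence

#: default per-row peak torso depth (cm), nipple line -> navel
BASE_PROFILE = PhantomConfig().torso_profile


def signal_recovery_trial(seed: int) -> PhantomConfig:
    """Uniform 1.5 cm breathing amplitude, exact 4 s period, 60 s.

    All per-cycle jitters are zero, so the trial contains exactly
    60 / 4 = 15 complete cycles and the clean central-channel peak-to-peak
    equals the configured 1.5 cm.
    """
    return PhantomConfig(breathing_amplitude=(1.5,) * 7, mean_period=4.0,
                         period_jitter=0.0, amplitude_jitter=0.0,
                         baseline_jitter=0.0, duration=60.0, seed=seed)


def artifact_trial(seed: int) -> PhantomConfig:
    """Regular breathing with two injected motion artifacts.

    A 2 s upper-body step-shift (grid rows 1-4) at t = 15 s and a 1.5 s
    lower-body spike (rows 4-7) at t = 40 s, both 1 cm — the scale of a trunk
    movement, well above the breathing amplitudes. Together the two events
    touch every monitored channel, as a trunk movement does.
    """
    return PhantomConfig(
        duration=60.0, seed=seed,
        artifacts=(
            ArtifactSpec(onset_time=15.0, duration=2.0, kind="step-shift",
                         magnitude=1.0, rows=(1, 2, 3, 4)),
            ArtifactSpec(onset_time=40.0, duration=1.5, kind="spike",
                         magnitude=1.0, rows=(4, 5, 6, 7)),
        ))


def gating_trial(seed: int) -> PhantomConfig:
    """Trial for gate-retention checks: long enough for a stable statistic.

    A 2 min recording at a 25 breaths-per-minute rate (typical for a young
    child) leaves well over 20 breaths after artifact removal, so the
    retained fraction of an in-distribution gate is resolved finer than one
    breath. Gating a session against an identical session must keep >= 95%
    of its breaths; a session whose features are shifted by 10 SDs must be
    rejected almost entirely.
    """
    return PhantomConfig(duration=120.0, mean_period=2.4, period_jitter=0.24,
                         seed=seed)


def _scaled(scale: float, **kwargs) -> PhantomConfig:
    profile = tuple(scale * np.asarray(BASE_PROFILE))
    amplitude = tuple(scale * np.asarray(PhantomConfig().breathing_amplitude))
    return PhantomConfig(torso_profile=profile, breathing_amplitude=amplitude,
                         amplitude_jitter=0.05, baseline_jitter=0.03,
                         duration=60.0, **kwargs)


def morphology_change_pair(seed: int,
                           change_percent: float = 3.0
                           ) -> tuple[PhantomConfig, PhantomConfig]:
    """Two sessions of one subject whose torso grew by ``change_percent``.

    Session 2 scales the static profile and the breathing amplitudes
    together, so every transverse cross-section area — at any level and
    breathing phase — is exactly ``change_percent`` % larger.
    """
    scale = 1.0 + change_percent / 100.0
    return _scaled(1.0, seed=seed), _scaled(scale, seed=seed + 1)


def chest_mobility_trial(seed: int, mobility_percent: float = 4.0) -> PhantomConfig:
    """Breathing amplitude a fixed fraction of the static profile per row.

    With amplitude = f * profile the inspiration cross-section area exceeds
    the expiration area by f * s_max at every level, i.e. the configured
    chest mobility Dsess is ``mobility_percent`` % (up to the small per-cycle
    gain scatter).
    """
    f = mobility_percent / 100.0
    return PhantomConfig(breathing_amplitude=tuple(f * np.asarray(BASE_PROFILE)),
                         amplitude_jitter=0.05, baseline_jitter=0.03,
                         duration=60.0, seed=seed)


def noise_free_trial(seed: int, noise_sigma: float = 0.0) -> PhantomConfig:
    """Fully deterministic breathing; ``noise_sigma`` is the only randomness.

    The 4 s period is an exact 120-sample cycle at 30 fps, so with zero noise
    every breath is sample-identical and all CVs are exactly zero.
    """
    return PhantomConfig(breathing_amplitude=(0.5,) * 7, mean_period=4.0,
                         period_jitter=0.0, amplitude_jitter=0.0,
                         baseline_jitter=0.0, noise_sigma=noise_sigma,
                         duration=40.0, seed=seed)


def random_pose_trial(rng: np.random.Generator, seed: int,
                      duration: float = 0.5) -> PhantomConfig:
    """Short trial under a random camera pose (tilt, yaw, offset)."""
    return PhantomConfig(
        tilt=(float(rng.uniform(-5, 5)), float(rng.uniform(-5, 5))),
        yaw=float(rng.uniform(-10, 10)),
        offset=tuple(float(v) for v in rng.uniform(-2, 2, size=3)),
        duration=duration, seed=seed)


class BreathStageResult:
    """Products of the signal chain up to breath segmentation."""

    def __init__(self, signals, grid, breaths, smoothed_central, minima, maxima):
        self.signals = signals
        self.grid = grid
        self.breaths = breaths
        self.smoothed_central = smoothed_central
        self.minima = minima
        self.maxima = maxima


def run_phantom_breaths(config: PhantomConfig,
                        run_config: RunConfig | None = None) -> BreathStageResult:
    """Signal chain up to breath segmentation only (no artifact removal).

    Used by scenarios that inject no artifacts and study a signal-level
    property (amplitude recovery, cycle count, noise propagation into CVs):
    the percentile artifact rule always flags the top 1% of every channel,
    and on a trial whose criterion is near-periodic (deterministic breathing)
    or noise-dominated those flags can scatter across every breath, so the
    artifact-removal and gating stages are deliberately not applied here.
    """
    from chestmorph.geometry import (build_grid, compute_alignment,
                                     extract_depth_signals, fit_table_plane)
    from chestmorph.respiration import (detect_extrema, separate_breaths,
                                        smooth)

    rc = run_config or RunConfig()
    sequence, gt = generate_sequence(config)
    tracks = true_marker_tracks(gt)
    plane = fit_table_plane(sequence[0], table_roi_box(config),
                            min_points=rc.min_table_points,
                            max_residual=rc.max_plane_residual_cm)
    signals = extract_depth_signals(sequence, tracks, plane, rc)
    central = smooth(signals.central_signal, signals.frame_rate,
                     cutoff_hz=rc.filter_cutoff_hz, order=rc.filter_order)
    minima, maxima = detect_extrema(central)
    breaths = separate_breaths(central, minima, maxima, signals.frame_rate)
    transform = compute_alignment(tracks[0], plane)
    grid = build_grid(transform.apply_marker_triplet(tracks[0]),
                      roi_half_size=rc.roi_half_size_cm,
                      rows_of_interest=rc.rows_of_interest)
    return BreathStageResult(signals, grid, breaths, central, minima, maxima)


def run_phantom(config: PhantomConfig, run_config: RunConfig | None = None,
                use_true_tracks: bool = True) -> tuple[SessionResult, object]:
    """Generate and process one phantom trial; returns (result, ground truth).

    ``use_true_tracks`` feeds the phantom's exact marker tracks to the
    pipeline, isolating the signal/respiration/cross-section stages from the
    Hough tracker (which has its own validation).
    """
    sequence, gt = generate_sequence(config)
    tracks = true_marker_tracks(gt) if use_true_tracks else None
    seed_triplet = None
    if not use_true_tracks:
        from chestmorph.phantom import operator_seed
        seed_triplet = operator_seed(gt)
    result = process_sequence(sequence, seed_triplet, table_roi_box(config),
                              run_config or RunConfig(), marker_tracks=tracks)
    return result, gt
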