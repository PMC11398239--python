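"""End-to-end orchestration: frames -> signals -> breaths -> cross-sections.

``process_sequence`` runs marker tracking, alignment and signal extraction and
cleans the breaths for one trial/session; ``analyze_session`` (optionally
gated against a second session) derives the cross-section groups, outlier
flags, representative curves, CVs and chest mobility; ``compare_sessions``
gates two sessions jointly and reports the inter-session morphology change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from chestmorph._version import __version__ as _version
from chestmorph.config import RunConfig
from chestmorph.cross_section import (
    LEVEL_NAMES,
    LEVELS,
    PHASES,
    CrossSectionGroup,
    RepresentativeSet,
    build_groups,
    chest_mobility,
    dispersion,
    flag_outliers,
    morphology_change,
    select_representative,
)
from chestmorph.geometry import (
    DepthSignalSet,
    TablePlane,
    build_grid,
    compute_alignment,
    extract_depth_signals,
    fit_table_plane,
)
from chestmorph.io import FrameSequence, ROIBox
from chestmorph.markers import MarkerTriplet, track_markers
from chestmorph.respiration import (
    BreathSegment,
    breath_features,
    detect_artifact_samples,
    detect_extrema,
    gate_breaths,
    remove_artifact_breaths,
    separate_breaths,
    smooth,
)

log = logging.getLogger(__name__)


@dataclass
class SessionResult:
    """Signal-level products of one processed trial/session."""

    plane: TablePlane
    marker_tracks: list[MarkerTriplet]
    signals: DepthSignalSet
    smoothed_central: np.ndarray
    minima: np.ndarray
    maxima: np.ndarray
    breaths_initial: list[BreathSegment]
    breaths_retained: list[BreathSegment]
    breaths_removed: list[BreathSegment]
    artifact_masks: dict
    merged_artifact_mask: np.ndarray
    config: RunConfig

    @property
    def features(self) -> np.ndarray:
        return breath_features(self.breaths_retained)

    def grid(self):
        """Channel grid of the first frame's aligned markers (node positions)."""
        transform = compute_alignment(self.marker_tracks[0], self.plane)
        return build_grid(transform.apply_marker_triplet(self.marker_tracks[0]),
                          roi_half_size=self.config.roi_half_size_cm,
                          rows_of_interest=self.config.rows_of_interest)


def process_sequence(sequence: FrameSequence,
                     operator_seed: MarkerTriplet | None,
                     table_region: ROIBox | list[ROIBox],
                     config: RunConfig | None = None,
                     marker_tracks: list[MarkerTriplet] | None = None) -> SessionResult:
    """Run the signal-level chain on one sequence.

    ``marker_tracks`` may be supplied (e.g. from a previous run or a phantom's
    ground truth) to skip detection; otherwise ``operator_seed`` initializes
    Hough tracking on the first frame.
    """
    config = config or RunConfig()
    config.validate()
    if marker_tracks is None:
        if operator_seed is None:
            raise ValueError("either an operator seed or precomputed marker "
                             "tracks are required")
        marker_tracks = track_markers(sequence, operator_seed, config)
    plane = fit_table_plane(sequence[0], table_region,
                            min_points=config.min_table_points,
                            max_residual=config.max_plane_residual_cm)
    signals = extract_depth_signals(sequence, marker_tracks, plane, config)
    central = smooth(signals.central_signal, signals.frame_rate,
                     cutoff_hz=config.filter_cutoff_hz, order=config.filter_order)
    minima, maxima = detect_extrema(central)
    breaths = separate_breaths(central, minima, maxima, signals.frame_rate)
    masks, merged = detect_artifact_samples(signals, config)
    retained, removed = remove_artifact_breaths(breaths, merged)
    log.info("breaths initial=%d retained=%d removed=%d",
             len(breaths), len(retained), len(removed))
    return SessionResult(plane=plane, marker_tracks=marker_tracks, signals=signals,
                         smoothed_central=central, minima=minima, maxima=maxima,
                         breaths_initial=breaths, breaths_retained=retained,
                         breaths_removed=removed, artifact_masks=masks,
                         merged_artifact_mask=merged, config=config)


@dataclass
class SessionAnalysis:
    """Cross-section-level products of one session after gating."""

    gated_breaths: list[BreathSegment]
    groups: dict[str, dict[int, CrossSectionGroup]]
    representatives: dict[str, RepresentativeSet]
    cv_location: dict[str, dict[int, np.ndarray]]
    cv_area: dict[str, dict[int, float]]
    dsess: dict[int, float]

    def report(self) -> dict:
        rep = {}
        for phase in PHASES:
            rep[phase] = {
                LEVEL_NAMES[lv]: {
                    "clean_count": len(self.groups[phase][lv].clean_members()),
                    "total_count": len(self.groups[phase][lv]),
                    "cv_location_percent": list(np.round(self.cv_location[phase][lv], 6)),
                    "cv_area_percent": round(self.cv_area[phase][lv], 6),
                    "representative_area_cm2": self.representatives[phase].areas[lv],
                    "representative_depths_cm":
                        list(self.representatives[phase].sections[lv].node_depths),
                } for lv in LEVELS
            }
        rep["chest_mobility_percent"] = {LEVEL_NAMES[lv]: self.dsess[lv] for lv in LEVELS}
        rep["gated_breath_count"] = len(self.gated_breaths)
        return rep


def analyze_session(result: SessionResult, gate_mask: np.ndarray | None = None,
                    config: RunConfig | None = None) -> SessionAnalysis:
    """Build, clean and summarize the cross-sections of one session.

    ``gate_mask`` selects the gated breaths (from :func:`gate_breaths`); when
    omitted the session self-gates against its own feature model.
    """
    config = config or result.config
    if gate_mask is None:
        gate_mask, _, _ = gate_breaths(result.features, None,
                                       floor=config.membership_floor)
    gated = [b for b, keep in zip(result.breaths_retained, gate_mask) if keep]
    if not gated:
        raise RuntimeError("gating removed every breath")
    grid = result.grid()
    groups = build_groups(result.signals, grid, gated)
    for phase in PHASES:
        flag_outliers(groups[phase], iqr_factor=config.iqr_factor)
    reps = {phase: select_representative(groups[phase], phase) for phase in PHASES}
    cv_loc: dict[str, dict[int, np.ndarray]] = {p: {} for p in PHASES}
    cv_area: dict[str, dict[int, float]] = {p: {} for p in PHASES}
    for phase in PHASES:
        for lv in LEVELS:
            cv_loc[phase][lv], cv_area[phase][lv] = dispersion(groups[phase][lv])
    dsess = chest_mobility(reps["inspiration"], reps["expiration"])
    return SessionAnalysis(gated_breaths=gated, groups=groups, representatives=reps,
                           cv_location=cv_loc, cv_area=cv_area, dsess=dsess)


@dataclass
class ComparisonResult:
    """Joint gating of two sessions plus the inter-session change metrics."""

    analysis1: SessionAnalysis
    analysis2: SessionAnalysis
    morphology_change: dict[str, dict[int, float]]  # phase -> level -> D (%)

    def report(self, config: RunConfig | None = None) -> dict:
        rep = {
            "session1": self.analysis1.report(),
            "session2": self.analysis2.report(),
            "morphology_change_percent": {
                phase: {LEVEL_NAMES[lv]: d[lv] for lv in LEVELS}
                for phase, d in self.morphology_change.items()
            },
            "tool_version": _version,
        }
        if config is not None:
            rep["config"] = config.to_dict()
        return rep


def compare_sessions(result1: SessionResult, result2: SessionResult,
                     config: RunConfig | None = None) -> ComparisonResult:
    """Gate the two sessions against each other and compare their morphology."""
    config = config or result1.config
    keep1, keep2, _ = gate_breaths(result1.features, result2.features,
                                   floor=config.membership_floor)
    a1 = analyze_session(result1, keep1, config)
    a2 = analyze_session(result2, keep2, config)
    change = {phase: morphology_change(a1.representatives[phase],
                                       a2.representatives[phase])
              for phase in PHASES}
    return ComparisonResult(analysis1=a1, analysis2=a2, morphology_change=change)
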