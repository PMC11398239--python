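"""Transverse cross-sections, outlier cascade, representatives and metrics.

For every retained breath, the depth-variation values of one grid row at the
breath's inspiration (central maximum) or expiration (bounding minimum)
sample form a 7-node transverse cross-section (CS); CS1/CS2/CS3 are grid
rows 1/3/5. Within a group (one level, one phase) a CS is an outlier if any
node falls outside the per-location 1.5 IQR fences; outlier flags propagate
to the same-time-sample CSs at the other levels. The representative triplet
is the medoid of the clean triplets in (area_CS1, area_CS2, area_CS3) space.
Reliability is the coefficient of variation per location and of the CS area;
chest mobility is the percentage excess of the representative inspiration
area over expiration (within a session), and morphology change the
percentage area change between sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from chestmorph.geometry import ChannelGrid, DepthSignalSet
from chestmorph.respiration import BreathSegment

LEVELS = (1, 3, 5)          # grid rows of CS1, CS2, CS3
PHASES = ("inspiration", "expiration")
LEVEL_NAMES = {1: "CS1", 3: "CS2", 5: "CS3"}


class CrossSectionError(RuntimeError):
    pass


@dataclass
class CrossSection:
    """One 7-node transverse depth profile."""

    level: int                    # grid row: 1, 3 or 5
    phase: str                    # "inspiration" | "expiration"
    node_positions: np.ndarray    # 7 y-coordinates, strictly increasing (cm)
    node_depths: np.ndarray       # 7 depths (cm)
    breath_id: int
    sample_index: int

    def __post_init__(self) -> None:
        self.node_positions = np.asarray(self.node_positions, dtype=np.float64)
        self.node_depths = np.asarray(self.node_depths, dtype=np.float64)
        if self.node_positions.shape != (7,) or self.node_depths.shape != (7,):
            raise ValueError("a cross-section has exactly 7 nodes")
        if not np.all(np.diff(self.node_positions) > 0):
            raise ValueError("node positions must be strictly increasing")
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")


def extract_cs(signals: DepthSignalSet, grid: ChannelGrid, breath: BreathSegment,
               level: int, phase: str) -> CrossSection:
    """CS nodes = r at the breath's inspiration maximum / expiration end minimum."""
    idx = breath.max_index if phase == "inspiration" else breath.end_min_index
    n = signals.n_samples
    if not 0 <= idx < n:
        raise CrossSectionError(f"sample index {idx} out of range (n={n})")
    depths = np.array([signals.r[(level, j)][idx] for j in range(1, 8)])
    return CrossSection(level=level, phase=phase,
                        node_positions=grid.col_y.copy(), node_depths=depths,
                        breath_id=breath.breath_id, sample_index=idx)


def interpolate_cs(cs: CrossSection, positions) -> np.ndarray:
    """Piecewise-linear depth at query positions inside [node 1, node 7]."""
    q = np.atleast_1d(np.asarray(positions, dtype=np.float64))
    lo, hi = cs.node_positions[0], cs.node_positions[-1]
    if np.any(q < lo) or np.any(q > hi):
        raise CrossSectionError("extrapolation outside the cross-section span")
    return np.interp(q, cs.node_positions, cs.node_depths)


def cs_area(cs: CrossSection) -> float:
    """Area under the piecewise-linear depth curve (trapezoidal rule, exact)."""
    return float(np.trapezoid(cs.node_depths, cs.node_positions))


@dataclass
class CrossSectionGroup:
    """All CSs of one level and phase, with outlier flags."""

    level: int
    phase: str
    members: list[CrossSection]
    outlier: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.outlier is None:
            self.outlier = np.zeros(len(self.members), dtype=bool)
        self.outlier = np.asarray(self.outlier, dtype=bool)
        if len(self.outlier) != len(self.members):
            raise ValueError("one outlier flag per member required")

    def __len__(self) -> int:
        return len(self.members)

    def clean_members(self) -> list[CrossSection]:
        return [m for m, bad in zip(self.members, self.outlier) if not bad]

    def areas(self, clean_only: bool = True) -> np.ndarray:
        members = self.clean_members() if clean_only else self.members
        return np.array([cs_area(m) for m in members])

    def depth_matrix(self, clean_only: bool = True) -> np.ndarray:
        members = self.clean_members() if clean_only else self.members
        return np.array([m.node_depths for m in members])


def build_groups(signals: DepthSignalSet, grid: ChannelGrid,
                 breaths: list[BreathSegment]) -> dict[str, dict[int, CrossSectionGroup]]:
    """CS groups for every phase and level from the retained breaths."""
    groups: dict[str, dict[int, CrossSectionGroup]] = {}
    for phase in PHASES:
        groups[phase] = {
            level: CrossSectionGroup(level, phase,
                                     [extract_cs(signals, grid, b, level, phase)
                                      for b in breaths])
            for level in LEVELS
        }
    return groups


# --------------------------------------------------------------- outliers

def _fence_flags(group: CrossSectionGroup, factor: float) -> np.ndarray:
    """Single-pass per-location IQR fences over the full (unflagged) group."""
    depths = group.depth_matrix(clean_only=False)
    q1 = np.percentile(depths, 25, axis=0)
    q3 = np.percentile(depths, 75, axis=0)
    iqr = q3 - q1
    lo, hi = q1 - factor * iqr, q3 + factor * iqr
    return ((depths < lo) | (depths > hi)).any(axis=1)


def flag_outliers(groups_by_level: dict[int, CrossSectionGroup],
                  iqr_factor: float = 1.5) -> dict[int, CrossSectionGroup]:
    """Flag IQR outliers per level and propagate flags across levels.

    Fences are computed once from the original groups (a single detection
    pass); a CS flagged at any level flags its same-time-sample partners at
    the other levels, iterated to a fixed point. Groups are updated in place
    and returned.
    """
    for g in groups_by_level.values():
        if len(g) < 4:
            raise CrossSectionError("need at least 4 cross-sections per group "
                                    "to compute quartiles")
    flagged_samples: set[int] = set()
    for level, g in groups_by_level.items():
        direct = _fence_flags(g, iqr_factor)
        g.outlier = g.outlier | direct
        flagged_samples |= {m.sample_index for m, bad in zip(g.members, direct) if bad}
    # propagation: a flagged time sample is an outlier at every level
    changed = True
    while changed:
        changed = False
        for g in groups_by_level.values():
            for k, m in enumerate(g.members):
                if m.sample_index in flagged_samples and not g.outlier[k]:
                    g.outlier[k] = True
                    changed = True
    return groups_by_level


# ---------------------------------------------------------- representative

@dataclass
class RepresentativeSet:
    """The medoid triplet of one phase: CS1/CS2/CS3 from one time sample."""

    phase: str
    sample_index: int
    sections: dict[int, CrossSection]
    areas: dict[int, float]


def select_representative(groups_by_level: dict[int, CrossSectionGroup],
                          phase: str) -> RepresentativeSet:
    """Medoid of the clean triplets in (area1, area2, area3) space.

    The triplet minimizing the summed Euclidean distance to all other
    triplets is chosen; ties break to the earliest time sample.
    """
    by_sample: dict[int, dict[int, CrossSection]] = {}
    for level in LEVELS:
        for m in groups_by_level[level].clean_members():
            by_sample.setdefault(m.sample_index, {})[level] = m
    triplets = {s: d for s, d in by_sample.items() if len(d) == len(LEVELS)}
    if not triplets:
        raise CrossSectionError("no clean cross-section triplets remain")
    samples = sorted(triplets)
    pts = np.array([[cs_area(triplets[s][lv]) for lv in LEVELS] for s in samples])
    dist = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    total = dist.sum(axis=1)
    best = int(np.argmin(total))  # argmin returns the first (earliest) minimum
    s = samples[best]
    return RepresentativeSet(phase=phase, sample_index=s, sections=triplets[s],
                             areas={lv: float(pts[best, k]) for k, lv in enumerate(LEVELS)})


# ------------------------------------------------------------- dispersion

def dispersion(group: CrossSectionGroup) -> tuple[np.ndarray, float]:
    """(per-location CV %, area CV %) over the clean members (sample std)."""
    depths = group.depth_matrix(clean_only=True)
    if len(depths) < 2:
        raise CrossSectionError("need at least 2 clean cross-sections for a CV")
    means = depths.mean(axis=0)
    if np.any(means == 0):
        raise CrossSectionError("zero mean depth: CV undefined")
    cv_loc = 100.0 * depths.std(axis=0, ddof=1) / means
    areas = group.areas(clean_only=True)
    if areas.mean() == 0:
        raise CrossSectionError("zero mean area: CV undefined")
    cv_area = float(100.0 * areas.std(ddof=1) / areas.mean())
    return cv_loc, cv_area


# ---------------------------------------------------------------- metrics

def chest_mobility(rep_inspiration: RepresentativeSet,
                   rep_expiration: RepresentativeSet) -> dict[int, float]:
    """Dsess per level: 100 * (A_insp - A_exp) / A_exp within one session."""
    out = {}
    for level in LEVELS:
        a_min = rep_expiration.areas[level]
        a_max = rep_inspiration.areas[level]
        if a_min <= 0:
            raise CrossSectionError("non-positive expiration area")
        out[level] = 100.0 * (a_max - a_min) / a_min
    return out


def morphology_change(rep_session1: RepresentativeSet,
                      rep_session2: RepresentativeSet) -> dict[int, float]:
    """D per level: 100 * (A_sess2 - A_sess1) / A_sess1 for one phase."""
    out = {}
    for level in LEVELS:
        a1 = rep_session1.areas[level]
        a2 = rep_session2.areas[level]
        if a1 <= 0:
            raise CrossSectionError("non-positive session-1 area")
        out[level] = 100.0 * (a2 - a1) / a1
    return out


def groups_to_table(groups: dict[str, dict[int, CrossSectionGroup]], session: str = ""):
    """Long-format DataFrame of every CS node (for CSV export)."""
    import pandas as pd

    rows = []
    for phase, by_level in groups.items():
        for level, g in by_level.items():
            for m, bad in zip(g.members, g.outlier):
                for j in range(7):
                    rows.append({"session": session, "level": LEVEL_NAMES[level],
                                 "phase": phase, "breath_id": m.breath_id,
                                 "sample_index": m.sample_index, "j": j + 1,
                                 "y_cm": m.node_positions[j],
                                 "depth_cm": m.node_depths[j],
                                 "outlier_flag": bool(bad)})
    return pd.DataFrame(rows)
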