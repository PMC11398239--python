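"""CSV/JSON persistence of processed sessions.

A processed session directory holds ``session.json`` (frame rate, table
distance, grid geometry, resolved config, tool version), ``signals.csv`` (one
column per channel), ``breaths.csv``, ``markers.csv``, ``artifact_masks.csv``
and ``cross_sections.csv``; enough to re-gate and re-compare sessions without
the original point clouds.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from chestmorph._version import __version__ as _version
from chestmorph.config import RunConfig
from chestmorph.cross_section import build_groups
from chestmorph.geometry import ChannelGrid, DepthSignalSet
from chestmorph.respiration import BreathSegment, breath_features


def _channel_key(name: str) -> tuple[int, int]:
    _, i, j = name.split("_")
    return int(i), int(j)


def save_session(result, out_dir: str | Path, config: RunConfig | None = None) -> Path:
    """Persist a :class:`~chestmorph.pipeline.SessionResult`; returns the dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or result.config
    sig = result.signals
    grid = result.grid()

    sig.to_frame().to_csv(out / "signals.csv", index=False)

    pd.DataFrame({f"r_{i}_{j}": m for (i, j), m in result.artifact_masks.items()}
                 ).to_csv(out / "artifact_masks.csv", index=False)

    retained_ids = {b.breath_id for b in result.breaths_retained}
    rows = []
    for b in result.breaths_initial:
        rows.append({"breath_id": b.breath_id, "start_sample": b.start_min_index,
                     "max_sample": b.max_index, "end_sample": b.end_min_index,
                     "period_s": b.period, "amplitude_cm": b.amplitude,
                     "retained_flag": b.breath_id in retained_ids,
                     "removal_reason": "" if b.breath_id in retained_ids else "artifact"})
    pd.DataFrame(rows).to_csv(out / "breaths.csv", index=False)

    if result.marker_tracks:
        from chestmorph.markers import tracks_to_table
        tracks_to_table(result.marker_tracks).to_csv(out / "markers.csv", index=False)

    meta = {
        "tool_version": _version,
        "frame_rate_hz": sig.frame_rate,
        "camera_to_table_distance_cm": sig.d,
        "central_channel": list(sig.central),
        "grid_row_x_cm": list(grid.row_x),
        "grid_col_y_cm": list(grid.col_y),
        "roi_half_size_cm": grid.roi_half_size,
        "config": config.to_dict(),
    }
    with open(out / "session.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return out


class StoredSession:
    """A reloaded session: the subset of SessionResult that gating and
    cross-section analysis need (signals, retained breaths, grid, config)."""

    def __init__(self, signals: DepthSignalSet, breaths_retained: list[BreathSegment],
                 grid: ChannelGrid, config: RunConfig):
        self.signals = signals
        self.breaths_retained = breaths_retained
        self._grid = grid
        self.config = config

    @property
    def features(self) -> np.ndarray:
        return breath_features(self.breaths_retained)

    def grid(self) -> ChannelGrid:
        return self._grid


def load_session(session_dir: str | Path) -> StoredSession:
    d = Path(session_dir)
    if not (d / "session.json").exists():
        raise FileNotFoundError(f"not a processed session directory: {d}")
    with open(d / "session.json") as fh:
        meta = json.load(fh)
    config = RunConfig.from_dict(meta.get("config", {}))

    df = pd.read_csv(d / "signals.csv")
    r = {_channel_key(c): df[c].to_numpy() for c in df.columns}
    signals = DepthSignalSet(r=r, counts={k: np.zeros(len(v), dtype=int) for k, v in r.items()},
                             frame_rate=meta["frame_rate_hz"],
                             d=meta["camera_to_table_distance_cm"],
                             central=tuple(meta["central_channel"]))

    bdf = pd.read_csv(d / "breaths.csv")
    breaths = [BreathSegment(breath_id=int(row.breath_id),
                             start_min_index=int(row.start_sample),
                             max_index=int(row.max_sample),
                             end_min_index=int(row.end_sample),
                             period=float(row.period_s),
                             amplitude=float(row.amplitude_cm))
               for row in bdf.itertuples() if row.retained_flag]

    xs = np.asarray(meta["grid_row_x_cm"])
    ys = np.asarray(meta["grid_col_y_cm"])
    centers = np.stack(np.meshgrid(xs, ys, indexing="ij"), axis=-1)
    grid = ChannelGrid(centers=centers, roi_half_size=meta["roi_half_size_cm"],
                       rows_of_interest=tuple(config.rows_of_interest))
    return StoredSession(signals, breaths, grid, config)


def save_cross_sections(analysis, out_dir: str | Path, session: str = "") -> None:
    from chestmorph.cross_section import groups_to_table

    groups_to_table(analysis.groups, session=session).to_csv(
        Path(out_dir) / "cross_sections.csv", index=False)
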