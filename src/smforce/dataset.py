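"""Trajectory dataset container and delimited-text I/O.

A :class:`TrajectoryDataset` wraps a tidy :class:`pandas.DataFrame` with one
row per single-molecule observation, plus condition metadata and a
provenance log.  The on-disk form is a plain CSV next to a small JSON
sidecar (``<name>.meta.json``) holding metadata and log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = ["TrajectoryDataset", "TRAJECTORY_COLUMNS"]

#: Canonical column order of the trajectory-table schema.  ``efficiency`` may
#: contain values outside [0, 1] (corrected FRET efficiencies are noisy);
#: ``truth_*`` columns exist only for synthetic data.
TRAJECTORY_COLUMNS = [
    "track_id",
    "frame",
    "time_s",
    "x_um",
    "y_um",
    "i_donor",
    "i_acceptor",
    "efficiency",
    "cell_contact",
    "truth_force_pN",
    "truth_mobile",
]


@dataclass
class TrajectoryDataset:
    """Single-molecule tracks with per-observation data and provenance.

    Attributes
    ----------
    data:
        One row per observation.  Required columns: ``track_id``, ``frame``,
        ``time_s``, ``x_um``, ``y_um``; the rest of
        :data:`TRAJECTORY_COLUMNS` as available.
    metadata:
        Condition metadata (cell present/absent, bilayer phase, scanning vs
        activating, generator scenario, seeds, ...).
    log:
        Append-only provenance log (filter counts, processing steps).
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"track_id", "frame", "time_s", "x_um", "y_um"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"trajectory table missing columns: {sorted(missing)}")

    # -- basic accessors -------------------------------------------------
    @property
    def n_observations(self) -> int:
        return len(self.data)

    @property
    def n_tracks(self) -> int:
        return self.data["track_id"].nunique()

    def tracks(self) -> Iterator[tuple[int, pd.DataFrame]]:
        """Iterate ``(track_id, per-track frame)`` in track-id order."""
        return iter(self.data.groupby("track_id", sort=True))

    def track_values(self, column: str = "efficiency") -> list[np.ndarray]:
        """Per-track value arrays, dropping NaNs — the shape the
        track-preserving resampling routines consume."""
        out = []
        for _, g in self.data.groupby("track_id", sort=True):
            v = g[column].to_numpy(dtype=float)
            v = v[~np.isnan(v)]
            if v.size:
                out.append(v)
        return out

    def append_log(self, message: str) -> None:
        self.log.append(message)

    def validate(self) -> None:
        """Check structural invariants (strictly increasing frames per track)."""
        frames_ok = self.data.groupby("track_id")["frame"].apply(
            lambda f: bool(np.all(np.diff(f.to_numpy()) > 0))
        )
        if not frames_ok.all():
            bad = frames_ok.index[~frames_ok].tolist()
            raise ValueError(f"non-increasing frames within tracks: {bad[:5]}")
        for col in ("i_donor", "i_acceptor"):
            if col in self.data.columns:
                vals = self.data[col].to_numpy(dtype=float)
                if np.any(vals[~np.isnan(vals)] < 0):
                    raise ValueError(f"negative intensities in column {col}")

    def copy(self) -> "TrajectoryDataset":
        return TrajectoryDataset(self.data.copy(), dict(self.metadata), list(self.log))

    # -- I/O -------------------------------------------------------------
    def write(self, path: str | Path) -> None:
        """Write the table as CSV plus a ``.meta.json`` sidecar."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.data.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(
            json.dumps({"metadata": self.metadata, "log": self.log}, indent=2,
                       default=_json_default)
        )

    @classmethod
    def read(cls, path: str | Path) -> "TrajectoryDataset":
        path = Path(path)
        data = pd.read_csv(path)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        metadata, log = {}, []
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            metadata = meta.get("metadata", {})
            log = meta.get("log", [])
        return cls(data, metadata, log)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
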