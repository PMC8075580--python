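"""Localization tables, quality filtering, and frame-to-frame track linking.

Positions are in micrometres, localisation precision in nanometres, and
frames are 1-based integers. Trajectories are built by greedy
nearest-neighbour assignment between consecutive frames; a missing frame
always terminates a track (no gap closing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DuplicateLocalizationError, FormatError, ParseError

__all__ = [
    "Localization",
    "Trajectory",
    "filter_localizations",
    "link_trajectories",
    "read_locs_csv",
    "write_locs_csv",
    "read_spoton_csv",
    "write_spoton_csv",
]

LOC_COLUMNS = ("frame", "x", "y", "photons", "precision")
SPOTON_COLUMNS = ("frame", "t", "trajectory", "x", "y")


@dataclass(frozen=True)
class Localization:
    """One detected fluorophore appearance.

    Attributes
    ----------
    frame : int
        1-based frame index.
    x, y : float
        Position in micrometres.
    photons : float
        Signal photon count.
    precision : float
        Localisation precision in nanometres.
    """

    frame: int
    x: float
    y: float
    photons: float = 0.0
    precision: float = 1.0

    def __post_init__(self):
        if self.frame < 1:
            raise ValueError(f"frame must be >= 1, got {self.frame}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("x and y must be finite")
        if self.photons < 0:
            raise ValueError("photons must be >= 0")
        if self.precision <= 0:
            raise ValueError("precision must be > 0")


@dataclass
class Trajectory:
    """Ordered localizations in strictly consecutive frames of one molecule."""

    id: int
    points: list[Localization] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def frames(self) -> np.ndarray:
        return np.array([p.frame for p in self.points], dtype=int)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of positions in micrometres."""
        return np.array([[p.x, p.y] for p in self.points], dtype=float)

    def validate(self, max_jump: float | None = None) -> None:
        if len(self.points) < 1:
            raise ValueError("trajectory must contain at least one point")
        fr = self.frames
        if np.any(np.diff(fr) != 1):
            raise ValueError(f"trajectory {self.id}: frames not consecutive")
        if max_jump is not None and len(self.points) > 1:
            steps = np.linalg.norm(np.diff(self.xy, axis=0), axis=1)
            if np.any(steps > max_jump + 1e-12):
                raise ValueError(
                    f"trajectory {self.id}: step exceeds max_jump {max_jump}"
                )


def filter_localizations(
    locs: Sequence[Localization],
    min_photons: float = 20,
    max_precision: float = 40,
) -> list[Localization]:
    """Keep localizations with photons >= ``min_photons`` and precision
    <= ``max_precision`` (nm). Both thresholds are inclusive; order preserved."""
    if min_photons <= 0 or max_precision <= 0:
        raise ValueError("thresholds must be positive")
    return [
        loc
        for loc in locs
        if loc.photons >= min_photons and loc.precision <= max_precision
    ]


def link_trajectories(
    locs: Sequence[Localization], max_jump: float = 0.8
) -> list[Trajectory]:
    """Link localizations in consecutive frames into trajectories.

    Candidate links are pairs of localizations in frames f and f+1 with
    Euclidean distance <= ``max_jump`` (um). Links are accepted greedily in
    ascending distance order, each localization used at most once; exact
    distance ties break on lower input row index. Unlinked localizations
    start or terminate trajectories; a frame gap always terminates.
    """
    if max_jump <= 0:
        raise ValueError("max_jump must be positive")

    seen: set[tuple[int, float, float]] = set()
    for loc in locs:
        key = (loc.frame, loc.x, loc.y)
        if key in seen:
            raise DuplicateLocalizationError(
                f"duplicate localization at frame={loc.frame}, "
                f"x={loc.x}, y={loc.y}"
            )
        seen.add(key)

    # stable sort by frame, preserving input row order within a frame
    order = sorted(range(len(locs)), key=lambda i: locs[i].frame)
    by_frame: dict[int, list[int]] = {}
    for i in order:
        by_frame.setdefault(locs[i].frame, []).append(i)

    trajectories: list[Trajectory] = []
    # open trajectory index for each localization row that ends a live track
    open_traj: dict[int, int] = {}

    def start_traj(row: int) -> None:
        tid = len(trajectories)
        trajectories.append(Trajectory(id=tid, points=[locs[row]]))
        open_traj[row] = tid

    frames_present = sorted(by_frame)
    for fi, frame in enumerate(frames_present):
        if fi == 0:
            for row in by_frame[frame]:
                start_traj(row)
            continue
        prev_frame = frames_present[fi - 1]
        rows = by_frame[frame]
        if frame != prev_frame + 1:
            # gap: every live track terminates, all current rows start fresh
            open_traj = {}
            for row in rows:
                start_traj(row)
            continue

        prev_rows = list(open_traj.keys())
        candidates = []
        for i in prev_rows:
            pi = locs[i]
            for j in rows:
                pj = locs[j]
                d = math.hypot(pj.x - pi.x, pj.y - pi.y)
                if d <= max_jump:
                    candidates.append((d, i, j))
        candidates.sort()

        used_prev: set[int] = set()
        used_next: set[int] = set()
        links: dict[int, int] = {}
        for d, i, j in candidates:
            if i in used_prev or j in used_next:
                continue
            used_prev.add(i)
            used_next.add(j)
            links[j] = i

        new_open: dict[int, int] = {}
        for j in rows:
            if j in links:
                tid = open_traj[links[j]]
                trajectories[tid].points.append(locs[j])
                new_open[j] = tid
            else:
                tid = len(trajectories)
                trajectories.append(Trajectory(id=tid, points=[locs[j]]))
                new_open[j] = tid
        open_traj = new_open

    return trajectories


def _read_table(path, required: Iterable[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column '{col}' in {path}")
    out = {}
    for col in required:
        try:
            out[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            row = int(bad.index[bad.isna() & df[col].notna()][0]) + 2  # header + 1-based
            raise ParseError(
                f"non-numeric value in column '{col}' at row {row} of {path}"
            ) from None
    return pd.DataFrame(out)


def read_locs_csv(path) -> list[Localization]:
    """Read a localization table with header ``frame,x,y,photons,precision``."""
    df = _read_table(path, LOC_COLUMNS)
    return [
        Localization(
            frame=int(r.frame), x=float(r.x), y=float(r.y),
            photons=float(r.photons), precision=float(r.precision),
        )
        for r in df.itertuples(index=False)
    ]


def write_locs_csv(locs: Sequence[Localization], path) -> None:
    pd.DataFrame(
        [(l.frame, l.x, l.y, l.photons, l.precision) for l in locs],
        columns=list(LOC_COLUMNS),
    ).to_csv(path, index=False)


def read_spoton_csv(path) -> list[Trajectory]:
    """Read trajectories from the Spot-On CSV dialect
    (``frame,t,trajectory,x,y``; frame 1-based, t seconds, x/y um)."""
    df = _read_table(path, SPOTON_COLUMNS)
    trajs = []
    for tid, grp in df.groupby("trajectory", sort=True):
        grp = grp.sort_values("frame")
        points = [
            Localization(frame=int(r.frame), x=float(r.x), y=float(r.y))
            for r in grp.itertuples(index=False)
        ]
        trajs.append(Trajectory(id=int(tid), points=points))
    return trajs


def write_spoton_csv(trajs: Sequence[Trajectory], frame_interval: float, path) -> None:
    """Write trajectories in the Spot-On dialect; ``t = (frame - 1) * frame_interval``."""
    rows = []
    for traj in trajs:
        for p in traj.points:
            rows.append((p.frame, (p.frame - 1) * frame_interval, traj.id, p.x, p.y))
    pd.DataFrame(rows, columns=list(SPOTON_COLUMNS)).to_csv(path, index=False)
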