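"""Lag-resolved jump-length samples, PDF histograms and empirical CDFs.

For each lag k (1 .. n_timepoints-1), displacements |r_{i+k} - r_i| are
collected starting from each trajectory's first point, taking at most
``jumps_to_consider`` jumps per trajectory per lag. Displacements above
``max_jump`` are discarded. The empirical CDF is evaluated on the histogram
bin-edge grid so that model fitting compares on a fixed abscissa.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyDatasetError, IncompatibleDatasetsError
from .trajectories import Trajectory

__all__ = ["JumpLengthDataset", "compute_jump_dataset", "pool_datasets"]


@dataclass
class JumpLengthDataset:
    frame_interval: float
    n_timepoints: int
    jumps_to_consider: int
    bin_width: float
    max_jump: float
    samples: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def lag_indices(self) -> list[int]:
        return list(range(1, self.n_timepoints))

    @property
    def lags(self) -> list[float]:
        """Lag times in seconds."""
        return [k * self.frame_interval for k in self.lag_indices]

    @property
    def n_bins(self) -> int:
        return int(round(self.max_jump / self.bin_width))

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(0.0, self.max_jump, self.n_bins + 1)

    def n_jumps(self, lag: int) -> int:
        return len(self.samples.get(lag, ()))

    @property
    def total_jumps(self) -> int:
        return sum(len(s) for s in self.samples.values())

    def pdf(self, lag: int) -> np.ndarray:
        """Histogram density on the bin grid; integrates to 1 when jumps exist."""
        counts, _ = np.histogram(self.samples[lag], bins=self.bin_edges)
        n = counts.sum()
        if n == 0:
            return np.zeros_like(counts, dtype=float)
        return counts / (n * self.bin_width)

    def empirical_cdf(self, lag: int) -> np.ndarray:
        """Empirical CDF of the retained samples, evaluated on the bin edges."""
        s = np.sort(self.samples[lag])
        if len(s) == 0:
            return np.zeros(self.n_bins + 1)
        return np.searchsorted(s, self.bin_edges, side="right") / len(s)

    def _binning_key(self):
        return (
            self.frame_interval,
            self.n_timepoints,
            self.jumps_to_consider,
            self.bin_width,
            self.max_jump,
        )

    def to_samples_csv(self, path) -> None:
        rows = []
        for k in self.lag_indices:
            lag_s = k * self.frame_interval
            for d in self.samples.get(k, ()):
                rows.append((lag_s, d))
        pd.DataFrame(rows, columns=["lag_s", "displacement_um"]).to_csv(
            path, index=False
        )

    def summary(self) -> dict:
        return {
            "frame_interval_s": self.frame_interval,
            "n_timepoints": self.n_timepoints,
            "jumps_to_consider": self.jumps_to_consider,
            "bin_width_um": self.bin_width,
            "max_jump_um": self.max_jump,
            "n_jumps_per_lag": {str(k): self.n_jumps(k) for k in self.lag_indices},
            "total_jumps": self.total_jumps,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)


def compute_jump_dataset(
    trajs: Sequence[Trajectory],
    frame_interval: float = 0.02,
    n_timepoints: int = 5,
    jumps_to_consider: int = 4,
    bin_width: float = 0.01,
    max_jump: float = 3.0,
) -> JumpLengthDataset:
    """Build per-lag displacement samples from trajectories.

    Raises
    ------
    EmptyDatasetError
        If no trajectory has length >= 2.
    """
    if n_timepoints < 2:
        raise ValueError("n_timepoints must be >= 2")
    if not trajs:
        raise EmptyDatasetError("no trajectories given")

    samples: dict[int, list[float]] = {k: [] for k in range(1, n_timepoints)}
    any_jump = False
    for traj in trajs:
        xy = traj.xy
        n = len(xy)
        if n < 2:
            continue
        any_jump = True
        for k in range(1, n_timepoints):
            n_avail = n - k
            if n_avail <= 0:
                continue
            n_take = min(jumps_to_consider, n_avail)
            d = np.linalg.norm(xy[k : k + n_take] - xy[:n_take], axis=1)
            samples[k].extend(d[d <= max_jump])

    if not any_jump:
        raise EmptyDatasetError("no trajectory of length >= 2; no jumps to analyse")

    return JumpLengthDataset(
        frame_interval=frame_interval,
        n_timepoints=n_timepoints,
        jumps_to_consider=jumps_to_consider,
        bin_width=bin_width,
        max_jump=max_jump,
        samples={k: np.asarray(v, dtype=float) for k, v in samples.items()},
    )


def pool_datasets(datasets: Sequence[JumpLengthDataset]) -> JumpLengthDataset:
    """Concatenate samples of datasets sharing identical binning and lags."""
    if not datasets:
        raise ValueError("nothing to pool")
    first = datasets[0]
    for d in datasets[1:]:
        if d._binning_key() != first._binning_key():
            raise IncompatibleDatasetsError(
                f"cannot pool datasets with different binning: "
                f"{d._binning_key()} vs {first._binning_key()}"
            )
    pooled = {
        k: np.concatenate([d.samples.get(k, np.empty(0)) for d in datasets])
        for k in first.lag_indices
    }
    return JumpLengthDataset(
        frame_interval=first.frame_interval,
        n_timepoints=first.n_timepoints,
        jumps_to_consider=first.jumps_to_consider,
        bin_width=first.bin_width,
        max_jump=first.max_jump,
        samples=pooled,
    )
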