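"""Forward simulator of sptPALM trajectory data.

Molecules are assigned a diffusive state, perform 3-D Brownian motion
reflected at a spherical nuclear boundary, appear at a uniformly random
frame (photoconversion), bleach after a geometric number of frames, and are
observed only while inside the axial detection slab |z| <= dZ/2; the first
slab exit truncates the track (absorbing boundary, matching the survival
model used for defocalisation correction). Observed positions carry
Gaussian localisation error; photon counts and precision values are drawn
from configurable distributions so quality filters can be exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .trajectories import Localization

__all__ = [
    "SimulationConfig",
    "MoleculeTruth",
    "GroundTruth",
    "simulate_spt",
    "make_fixture",
    "FIXTURE_PRESETS",
]


@dataclass(frozen=True)
class SimulationConfig:
    n_molecules: int
    state_fractions: tuple[float, ...]
    state_d: tuple[float, ...]  # um^2/s
    seed: int
    switching: tuple[tuple[float, ...], ...] | None = None  # rate matrix, 1/s
    nucleus_radius: float | None = 1.0  # um; None = unconfined
    frame_interval: float = 0.02  # s
    sigma_loc: float = 0.035  # um
    bleach_mean_frames: float = 20.0
    dz: float | None = 0.9  # um; None = no axial loss
    n_frames: int = 20000
    photon_mean: float = 500.0
    precision_mean_nm: float = 25.0
    precision_sd_nm: float = 5.0

    def __post_init__(self):
        if len(self.state_fractions) != len(self.state_d):
            raise ConfigError(
                f"{len(self.state_fractions)} fractions but "
                f"{len(self.state_d)} diffusion coefficients"
            )
        if abs(sum(self.state_fractions) - 1.0) > 1e-9:
            raise ConfigError("state fractions must sum to 1")
        if any(f < 0 for f in self.state_fractions):
            raise ConfigError("state fractions must be >= 0")
        if any(d < 0 for d in self.state_d):
            raise ConfigError("diffusion coefficients must be >= 0")
        if self.nucleus_radius is not None and self.nucleus_radius <= 0:
            raise ConfigError("nucleus_radius must be positive")
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be positive")
        if self.switching is not None:
            q = np.asarray(self.switching, dtype=float)
            if q.shape != (len(self.state_d), len(self.state_d)):
                raise ConfigError("switching matrix shape must be n_states^2")
            off = q[~np.eye(q.shape[0], dtype=bool)]
            if np.any(off < 0):
                raise ConfigError("off-diagonal switching rates must be >= 0")


@dataclass
class MoleculeTruth:
    molecule: int
    start_frame: int
    states: np.ndarray  # per simulated frame
    xyz: np.ndarray  # (n, 3) true positions, um
    emitted: np.ndarray  # bool mask over simulated frames


@dataclass
class GroundTruth:
    config: SimulationConfig
    molecules: list[MoleculeTruth] = field(default_factory=list)

    def state_occupancy(self) -> np.ndarray:
        """Fraction of molecules starting in each state."""
        counts = np.zeros(len(self.config.state_d))
        for m in self.molecules:
            counts[m.states[0]] += 1
        return counts / max(len(self.molecules), 1)

    def to_csv(self, path) -> None:
        rows = []
        for m in self.molecules:
            for i in range(len(m.states)):
                rows.append(
                    (
                        m.molecule,
                        m.start_frame + i,
                        int(m.states[i]),
                        m.xyz[i, 0],
                        m.xyz[i, 1],
                        m.xyz[i, 2],
                        bool(m.emitted[i]),
                    )
                )
        pd.DataFrame(
            rows,
            columns=["molecule", "frame", "state", "x", "y", "z", "emitted"],
        ).to_csv(path, index=False)


def _reflect_sphere(pos: np.ndarray, radius: float) -> np.ndarray:
    """Reflect a point back inside a sphere across its surface."""
    r = np.linalg.norm(pos)
    # repeated reflection handles (rare) steps larger than the diameter
    while r > radius:
        pos = pos * ((2.0 * radius - r) / r)
        r = abs(2.0 * radius - r)
    return pos


def _sample_in_sphere(rng: np.random.Generator, radius: float) -> np.ndarray:
    while True:
        p = rng.uniform(-radius, radius, size=3)
        if np.dot(p, p) <= radius * radius:
            return p


def simulate_spt(
    config: SimulationConfig,
) -> tuple[list[Localization], GroundTruth]:
    """Simulate localizations and ground truth from ``config``.

    Fully reproducible: identical seeds give bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    n_states = len(config.state_d)
    fractions = np.asarray(config.state_fractions, dtype=float)
    dt = config.frame_interval
    R = config.nucleus_radius
    half_slab = None if config.dz is None else config.dz / 2.0

    # per-frame switching probabilities (first-order approximation)
    p_switch = None
    if config.switching is not None:
        q = np.asarray(config.switching, dtype=float)
        p_switch = q * dt
        np.fill_diagonal(p_switch, 0.0)
        p_switch[np.arange(n_states), np.arange(n_states)] = (
            1.0 - p_switch.sum(axis=1)
        )
        if np.any(p_switch < 0):
            raise ConfigError(
                "switching rates too fast for the frame interval "
                "(q*dt must leave a non-negative stay probability)"
            )

    locs: list[Localization] = []
    truth = GroundTruth(config=config)

    for mol in range(config.n_molecules):
        state = int(rng.choice(n_states, p=fractions))
        start_frame = int(rng.integers(1, config.n_frames + 1))
        bleach_len = int(rng.geometric(1.0 / config.bleach_mean_frames))
        n_steps = min(bleach_len, config.n_frames - start_frame + 1)

        if R is not None:
            pos = _sample_in_sphere(rng, R)
        else:
            # unconfined: scatter laterally; start z uniform in the slab so
            # the axial-survival model's uniform-entry assumption holds
            pos = rng.normal(0.0, 5.0, 3)
            if half_slab is not None:
                pos[2] = rng.uniform(-half_slab, half_slab)

        states = np.empty(n_steps, dtype=int)
        xyz = np.empty((n_steps, 3))
        emitted = np.zeros(n_steps, dtype=bool)
        in_slab = half_slab is None or abs(pos[2]) <= half_slab

        n_kept = 0
        for i in range(n_steps):
            if i > 0:
                if p_switch is not None:
                    state = int(rng.choice(n_states, p=p_switch[state]))
                step = rng.normal(0.0, np.sqrt(2.0 * config.state_d[state] * dt), 3)
                pos = pos + step
                if R is not None:
                    pos = _reflect_sphere(pos, R)
                if half_slab is not None and in_slab:
                    z0, z1 = float(xyz[i - 1, 2]), float(pos[2])
                    if abs(z1) > half_slab:
                        in_slab = False
                    else:
                        # Brownian-bridge probability that the path touched a
                        # slab face between frames even though both endpoints
                        # are inside: keeps the axial loss consistent with the
                        # continuous absorbing-boundary survival model
                        ddt = config.state_d[state] * dt
                        if ddt > 0:
                            p_up = np.exp(-(half_slab - z0) * (half_slab - z1) / ddt)
                            p_lo = np.exp(-(half_slab + z0) * (half_slab + z1) / ddt)
                            if rng.uniform() < min(p_up + p_lo, 1.0):
                                in_slab = False
            states[i] = state
            xyz[i] = pos
            n_kept = i + 1
            if not in_slab:
                break  # first slab exit truncates the track
            emitted[i] = True
            err = rng.normal(0.0, config.sigma_loc, 2)
            photons = rng.gamma(2.0, config.photon_mean / 2.0)
            precision = max(
                rng.normal(config.precision_mean_nm, config.precision_sd_nm), 2.0
            )
            locs.append(
                Localization(
                    frame=start_frame + i,
                    x=float(pos[0] + err[0]),
                    y=float(pos[1] + err[1]),
                    photons=float(photons),
                    precision=float(precision),
                )
            )

        truth.molecules.append(
            MoleculeTruth(
                molecule=mol,
                start_frame=start_frame,
                states=states[:n_kept],
                xyz=xyz[:n_kept],
                emitted=emitted[:n_kept],
            )
        )

    return locs, truth


FIXTURE_PRESETS = {
    # mixed bound / slow / free population, ~40% bound
    "nse4-like": dict(
        state_fractions=(0.40, 0.20, 0.40),
        state_d=(0.01, 0.15, 1.0),
    ),
    # two states, no intermediate, high bound fraction
    "cohesin-like": dict(
        state_fractions=(0.65, 0.35),
        state_d=(0.01, 1.0),
    ),
    "free-only": dict(state_fractions=(1.0,), state_d=(1.0,)),
    "bound-only": dict(state_fractions=(1.0,), state_d=(0.01,)),
}


def make_fixture(
    name: str, n_molecules: int = 3000, seed: int = 0, **overrides
) -> SimulationConfig:
    """Return a documented simulation config for a named preset."""
    if name not in FIXTURE_PRESETS:
        raise ConfigError(
            f"unknown preset '{name}'; choose from {sorted(FIXTURE_PRESETS)}"
        )
    base = dict(
        n_molecules=n_molecules,
        seed=seed,
        nucleus_radius=1.0,
        frame_interval=0.02,
        sigma_loc=0.035,
        dz=0.9,
        n_frames=20000,
        bleach_mean_frames=20.0,
    )
    base.update(FIXTURE_PRESETS[name])
    base.update(overrides)
    return SimulationConfig(**base)
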