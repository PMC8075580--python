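"""Multi-state Brownian jump-length mixture model with localisation error and
axial defocalisation correction, fitted to empirical CDFs; AIC model selection.

The single-state 2-D Brownian jump-length CDF at lag dt is

    P(|r| <= r) = 1 - exp(-r^2 / (4 (D dt + sigma^2)))

where sigma is the localisation error (um). Fast states are progressively
lost from the axial detection slab of depth dZ; the mixture weights are
re-normalised at each lag by the slab survival probability. The bound state
(lowest D, index 0) is exempt: bound molecules move with chromatin and have
negligible axial motion on these timescales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.special import ndtr

from .errors import FitError, IncomparableFitsError, ModelValidationError
from .jumplens import JumpLengthDataset

__all__ = [
    "DiffusionModel",
    "FitResult",
    "jump_cdf_single",
    "jump_pdf_single",
    "z_survival",
    "model_cdf",
    "model_pdf",
    "fit_model",
    "select_by_aic",
    "f_bound",
]

SIGMA_BOUNDS = (0.01, 0.075)  # um; brackets the 40 nm precision filter
D_BOUND_RANGE = (0.0005, 0.08)
D_FREE_RANGE = (0.15, 25.0)
D_SLOW_MAX = 1.0
D_SINGLE_RANGE = (0.0005, 25.0)
N_STARTS = 5


@dataclass(frozen=True)
class DiffusionModel:
    """Mixture of Brownian states (fractions, D ascending), shared sigma, dZ.

    ``defocalised[i]`` marks whether state i is subject to axial loss; the
    bound state (index 0) is exempt by default.
    """

    fractions: tuple[float, ...]
    diffusion: tuple[float, ...]  # um^2/s, ascending
    sigma: float  # um
    dz: float  # um
    defocalised: tuple[bool, ...] | None = None

    def __post_init__(self):
        if len(self.fractions) != len(self.diffusion):
            raise ModelValidationError("fractions and diffusion differ in length")
        if self.defocalised is None:
            flags = (False,) + (True,) * (len(self.diffusion) - 1)
            object.__setattr__(self, "defocalised", flags)
        elif len(self.defocalised) != len(self.diffusion):
            raise ModelValidationError("defocalised flags differ in length")
        self.validate()

    @property
    def n_states(self) -> int:
        return len(self.fractions)

    def validate(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        d = np.asarray(self.diffusion, dtype=float)
        if not np.isclose(f.sum(), 1.0, atol=1e-8):
            raise ModelValidationError(f"fractions sum to {f.sum()}, not 1")
        if np.any(f < -1e-12) or np.any(f > 1 + 1e-12):
            raise ModelValidationError("fractions must lie in [0, 1]")
        if np.any(d < 0):
            raise ModelValidationError("diffusion coefficients must be >= 0")
        if np.any(np.diff(d) < 0):
            raise ModelValidationError("states must be ordered by ascending D")
        if not (0.005 <= self.sigma <= 0.1):
            raise ModelValidationError(
                f"sigma {self.sigma} outside plausible range [0.005, 0.1] um"
            )
        if self.dz <= 0:
            raise ModelValidationError("dZ must be positive")


@dataclass(frozen=True)
class FitResult:
    model: DiffusionModel
    rss: float
    n_points: int
    k_params: int
    aic: float
    n_states: int
    converged: bool
    seed: int
    delta_aic: float | None = None
    start_diagnostics: tuple = field(default=(), compare=False, repr=False)


def jump_cdf_single(r, D: float, dt: float, sigma: float):
    """CDF of 2-D Brownian jump lengths at lag ``dt`` with localisation
    error ``sigma``: ``1 - exp(-r^2 / (4 (D dt + sigma^2)))``."""
    if D < 0 or sigma < 0:
        raise ValueError("D and sigma must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    r = np.asarray(r, dtype=float)
    s2 = 4.0 * (D * dt + sigma * sigma)
    return 1.0 - np.exp(-(r * r) / s2)


def jump_pdf_single(r, D: float, dt: float, sigma: float):
    """Density d/dr of :func:`jump_cdf_single` (a Rayleigh density)."""
    if D < 0 or sigma < 0:
        raise ValueError("D and sigma must be non-negative")
    r = np.asarray(r, dtype=float)
    a = 2.0 * (D * dt + sigma * sigma)
    return (r / a) * np.exp(-(r * r) / (2.0 * a))


def _phi(u):
    return np.exp(-0.5 * u * u) / np.sqrt(2.0 * np.pi)


def _psi(u):
    # antiderivative of the standard normal CDF: u*Phi(u) + phi(u)
    return u * ndtr(u) + _phi(u)


def _z_survival_images(alpha: float) -> float:
    """Slab survival from a uniform start via the method of images.

    Exact for all alpha = D*dt/dZ^2 but used for small alpha where the
    eigenseries converges slowly. With c = 1/sqrt(2*alpha), averaging the
    image-series survival over a uniform start gives
    (1/c) * sum_n [3 Psi((1-2n)c) - 3 Psi(-2nc) + Psi(-(2n+1)c) - Psi((2-2n)c)].
    """
    c = 1.0 / np.sqrt(2.0 * alpha)
    n = np.arange(-8, 9)
    total = (
        3.0 * _psi((1 - 2 * n) * c)
        - 3.0 * _psi(-2 * n * c)
        + _psi(-(2 * n + 1) * c)
        - _psi((2 - 2 * n) * c)
    ).sum()
    return float(total / c)


def z_survival(D: float, dt: float, dz: float, n_terms: int | None = None) -> float:
    """Probability that a molecule with diffusion coefficient ``D``, starting
    uniformly in an axial slab of depth ``dz`` with absorbing boundaries,
    has not left the slab after time ``dt``.

    Computed from the absorbing-slab eigenfunction series
    ``sum_{odd j} (8 / (j pi)^2) exp(-(j pi)^2 D dt / dz^2)``; for small
    ``D dt / dz^2`` (where the series converges slowly) an exact
    method-of-images form is used instead, unless ``n_terms`` forces the
    truncated series, in which case an accuracy warning is raised when the
    truncation error bound exceeds 1e-9.
    """
    if dz <= 0:
        raise ValueError("dz must be positive")
    if D < 0:
        raise ValueError("D must be non-negative")
    if D == 0 or dt == 0:
        return 1.0
    alpha = D * dt / (dz * dz)

    if n_terms is None:
        if alpha < 0.02:
            return _z_survival_images(alpha)
        j = np.arange(1, 201, 2, dtype=float)
    else:
        j = np.arange(1, 2 * n_terms, 2, dtype=float)
    pi2 = np.pi * np.pi
    terms = (8.0 / (pi2 * j * j)) * np.exp(-pi2 * alpha * j * j)
    total = float(terms.sum())
    if n_terms is not None:
        j_max = j[-1]
        tail_bound = (8.0 / (pi2 * j_max)) * np.exp(-pi2 * alpha * j_max * j_max)
        if tail_bound > 1e-9:
            warnings.warn(
                f"z_survival eigenseries truncated at {n_terms} terms has "
                f"error bound {tail_bound:.2e} > 1e-9 (alpha={alpha:.3g})",
                RuntimeWarning,
            )
    return min(total, 1.0)


def _lag_weights(
    model: DiffusionModel, dt: float, jumps_to_consider: int | None = None
) -> np.ndarray:
    """Defocalisation-renormalised mixture weights at lag ``dt``.

    With ``jumps_to_consider`` set, the survival factor for each defocalising
    state is averaged over the jump start offsets pooled per lag: since the
    first J jumps of each track are collected, a lag-dt jump starting at
    offset j requires in-slab survival for dt + j*dt, so the effective
    state weight is the mean survival over j = 0..J-1. With None, the
    plain single-lag survival z_survival(D, dt, dZ) is used.
    """
    return _mixture_weights(model, dt, jumps_to_consider, None)


def _mixture_weights(
    model: DiffusionModel,
    dt: float,
    jumps_to_consider: int | None,
    frame_interval: float | None,
) -> np.ndarray:
    if jumps_to_consider is not None:
        fi = frame_interval if frame_interval is not None else dt
        times = dt + fi * np.arange(jumps_to_consider)
    w = np.asarray(model.fractions, dtype=float).copy()
    for i, (D, flag) in enumerate(zip(model.diffusion, model.defocalised)):
        if flag:
            if jumps_to_consider is None:
                w[i] *= z_survival(D, dt, model.dz)
            else:
                w[i] *= float(np.mean([z_survival(D, t, model.dz) for t in times]))
    s = w.sum()
    if s <= 0:
        raise ModelValidationError("all mixture weights vanished after defocalisation")
    return w / s


def model_cdf(
    model: DiffusionModel,
    dt: float,
    r_grid,
    jumps_to_consider: int | None = None,
    frame_interval: float | None = None,
) -> np.ndarray:
    """Mixture jump-length CDF at lag ``dt`` on ``r_grid`` with
    defocalisation-renormalised weights (see :func:`_lag_weights`)."""
    model.validate()
    r_grid = np.asarray(r_grid, dtype=float)
    if np.any(np.diff(r_grid) < 0):
        raise ValueError("r_grid must be ascending")
    w = _mixture_weights(model, dt, jumps_to_consider, frame_interval)
    out = np.zeros_like(r_grid)
    for wi, D in zip(w, model.diffusion):
        out += wi * jump_cdf_single(r_grid, D, dt, model.sigma)
    return out


def model_pdf(
    model: DiffusionModel,
    dt: float,
    r_grid,
    jumps_to_consider: int | None = None,
    frame_interval: float | None = None,
) -> np.ndarray:
    """Mixture jump-length density at lag ``dt`` (for PDF-histogram overlays)."""
    model.validate()
    r_grid = np.asarray(r_grid, dtype=float)
    w = _mixture_weights(model, dt, jumps_to_consider, frame_interval)
    out = np.zeros_like(r_grid)
    for wi, D in zip(w, model.diffusion):
        out += wi * jump_pdf_single(r_grid, D, dt, model.sigma)
    return out


def _stick_break(u: np.ndarray) -> np.ndarray:
    """Map free variables in [0,1]^(n-1) onto the n-simplex."""
    fracs = []
    rest = 1.0
    for ui in u:
        fracs.append(rest * ui)
        rest *= 1.0 - ui
    fracs.append(rest)
    return np.asarray(fracs)


def _param_bounds(n_states: int, d_slow_min: float):
    lo, hi = [], []
    lo += [1e-6] * (n_states - 1)
    hi += [1.0 - 1e-6] * (n_states - 1)
    if n_states == 1:
        lo += [D_SINGLE_RANGE[0]]
        hi += [D_SINGLE_RANGE[1]]
    elif n_states == 2:
        lo += [D_BOUND_RANGE[0], D_FREE_RANGE[0]]
        hi += [D_BOUND_RANGE[1], D_FREE_RANGE[1]]
    else:
        lo += [D_BOUND_RANGE[0], d_slow_min, D_FREE_RANGE[0]]
        hi += [D_BOUND_RANGE[1], D_SLOW_MAX, D_FREE_RANGE[1]]
    lo += [SIGMA_BOUNDS[0]]
    hi += [SIGMA_BOUNDS[1]]
    return np.asarray(lo), np.asarray(hi)


def _theta_to_model(theta: np.ndarray, n_states: int, dz: float) -> DiffusionModel:
    u = theta[: n_states - 1]
    d = np.asarray(theta[n_states - 1 : 2 * n_states - 1], dtype=float)
    sigma = float(theta[-1])
    fracs = _stick_break(u)
    order = np.argsort(d, kind="stable")
    return DiffusionModel(
        fractions=tuple(float(f) for f in fracs[order]),
        diffusion=tuple(float(x) for x in d[order]),
        sigma=sigma,
        dz=dz,
    )


def fit_model(
    dataset: JumpLengthDataset,
    n_states: int,
    dz: float = 0.9,
    d_slow_min: float = 0.08,
    seed: int = 0,
) -> FitResult:
    """Least-squares fit of the mixture CDF to the dataset's empirical CDFs.

    Residuals are the concatenated differences [empirical CDF - model CDF]
    over all lags on the bin-edge grid. Five optimisation starts are drawn
    uniformly within the parameter bounds from ``seed``; the best RSS wins.
    """
    if n_states not in (1, 2, 3):
        raise ValueError("n_states must be 1, 2 or 3")
    lags = [k for k in dataset.lag_indices if dataset.n_jumps(k) > 0]
    if len(lags) < 2:
        raise ValueError("dataset must contain jumps at >= 2 lags")
    if dataset.total_jumps < 100:
        warnings.warn(
            f"only {dataset.total_jumps} jumps in dataset; fit may be unstable",
            RuntimeWarning,
        )

    grid = dataset.bin_edges
    emp = {k: dataset.empirical_cdf(k) for k in lags}
    dts = {k: k * dataset.frame_interval for k in lags}

    # precompute nothing model-dependent; residual closure below
    def residuals(theta):
        model = _theta_to_model(theta, n_states, dz)
        res = []
        for k in lags:
            res.append(
                emp[k]
                - model_cdf(
                    model,
                    dts[k],
                    grid,
                    jumps_to_consider=dataset.jumps_to_consider,
                    frame_interval=dataset.frame_interval,
                )
            )
        return np.concatenate(res)

    lo, hi = _param_bounds(n_states, d_slow_min)
    rng = np.random.default_rng(seed)
    starts = [lo + rng.uniform(size=lo.size) * (hi - lo) for _ in range(N_STARTS)]

    best = None
    diagnostics = []
    for x0 in starts:
        try:
            sol = optimize.least_squares(
                residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-10, ftol=1e-10
            )
        except Exception as exc:  # pragma: no cover - defensive
            diagnostics.append({"x0": x0.tolist(), "error": str(exc)})
            continue
        rss = float(2.0 * sol.cost)
        diagnostics.append(
            {"x0": x0.tolist(), "rss": rss, "success": bool(sol.success)}
        )
        if sol.success and (best is None or rss < best[0]):
            best = (rss, sol)

    if best is None:
        raise FitError("all optimisation starts failed", diagnostics)

    rss, sol = best
    model = _theta_to_model(sol.x, n_states, dz)
    n_points = sum(len(emp[k]) for k in lags)
    k_params = 2 * n_states
    aic = n_points * np.log(rss / n_points) + 2 * k_params
    return FitResult(
        model=model,
        rss=rss,
        n_points=n_points,
        k_params=k_params,
        aic=float(aic),
        n_states=n_states,
        converged=True,
        seed=seed,
        start_diagnostics=tuple(
            tuple(sorted(d.items())) for d in diagnostics
        ),
    )


def select_by_aic(fit2: FitResult, fit3: FitResult) -> FitResult:
    """Return the fit with the lower AIC; ``delta_aic`` on the winner records
    |AIC difference|. Ties favour the model with fewer states."""
    if fit2.n_points != fit3.n_points:
        raise IncomparableFitsError(
            f"fits have different residual lengths "
            f"({fit2.n_points} vs {fit3.n_points}); not comparable"
        )
    delta = abs(fit2.aic - fit3.aic)
    simpler, other = sorted((fit2, fit3), key=lambda f: f.n_states)
    winner = simpler if simpler.aic <= other.aic else other
    return replace(winner, delta_aic=float(delta))


def f_bound(fit: FitResult) -> float:
    """Fraction of the lowest-D (chromatin-bound) state."""
    i = int(np.argmin(fit.model.diffusion))
    return float(fit.model.fractions[i])
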