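"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from sptkin.trajectories import Localization


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_loc(frame, x, y, photons=100.0, precision=20.0):
    return Localization(frame=frame, x=x, y=y, photons=photons, precision=precision)


# ---------------------------------------------------------------------------
# independent oracles (kept free of the implementation paths they check)
# ---------------------------------------------------------------------------

def brute_force_min_distance_matching(prev_pts, next_pts, max_jump):
    """All maximum-cardinality matchings with every pair within ``max_jump``;
    returns (best_total_distance, list of optimal matchings as sets of (i, j)).
    Enumeration over all injective assignments; exponential, tiny inputs only.
    """
    n_prev, n_next = len(prev_pts), len(next_pts)
    dist = {
        (i, j): float(np.hypot(prev_pts[i][0] - next_pts[j][0],
                               prev_pts[i][1] - next_pts[j][1]))
        for i in range(n_prev)
        for j in range(n_next)
    }
    allowed = {k for k, d in dist.items() if d <= max_jump}
    best_card = -1
    best = {}
    for r in range(min(n_prev, n_next), -1, -1):
        for prev_sub in itertools.combinations(range(n_prev), r):
            for next_perm in itertools.permutations(range(n_next), r):
                pairs = set(zip(prev_sub, next_perm))
                if not pairs <= allowed:
                    continue
                total = sum(dist[p] for p in pairs)
                if r > best_card:
                    best_card, best = r, {}
                if r == best_card:
                    best.setdefault(round(total, 12), []).append(pairs)
        if best_card == r and best:
            break
    if not best:
        return 0.0, [set()]
    t = min(best)
    return t, best[t]


def mc_slab_survival(D, dt, dz, n_walkers, rng, n_steps=200):
    """Brute-force absorbing random walk in z: walkers start uniform in the
    slab, take Euler steps of dt/n_steps, and are absorbed on exit; a
    Brownian-bridge crossing test removes the discretisation bias.
    Returns (survival fraction, Monte-Carlo standard error)."""
    h = dt / n_steps
    b = dz / 2.0
    z = rng.uniform(-b, b, n_walkers)
    alive = np.ones(n_walkers, dtype=bool)
    for _ in range(n_steps):
        idx = np.where(alive)[0]
        if idx.size == 0:
            break
        z0 = z[idx]
        z1 = z0 + rng.normal(0.0, np.sqrt(2.0 * D * h), idx.size)
        p_up = np.exp(-np.maximum(b - z0, 0) * np.maximum(b - z1, 0) / (D * h))
        p_lo = np.exp(-np.maximum(b + z0, 0) * np.maximum(b + z1, 0) / (D * h))
        killed = (
            (np.abs(z1) > b)
            | (rng.uniform(size=idx.size) < p_up)
            | (rng.uniform(size=idx.size) < p_lo)
        )
        z[idx] = z1
        alive[idx[killed]] = False
    p = alive.mean()
    return float(p), float(np.sqrt(p * (1.0 - p) / n_walkers))


def simulate_ld_cultures(m, eps, n_cultures, rng):
    """Brute-force Luria-Delbruck cultures: Poisson(m) mutation events per
    culture, deterministic clone growth (clone size floor(1/U), so
    P(size = j) = 1/(j(j+1))), binomial thinning at plating efficiency eps."""
    k = rng.poisson(m, n_cultures)
    counts = np.zeros(n_cultures, dtype=int)
    for i, ki in enumerate(k):
        if ki == 0:
            continue
        sizes = np.floor(1.0 / rng.uniform(size=ki)).astype(np.int64)
        if eps < 1.0:
            counts[i] = int(rng.binomial(sizes, eps).sum())
        else:
            counts[i] = int(sizes.sum())
    return counts
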