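"""Synthetic inputs with known ground truth.

Every estimator and descriptor in the package can be exercised without
running any molecular dynamics: a Gillespie birth-death process stands
in for the largest-cluster-size series (its barrier position, drift
crossing and first-passage statistics are known in closed form), and a
set of deterministic geometric configurations provides clusters whose
descriptors and partitions are known by construction.  None of the
fixtures attempts thermodynamic realism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import SystemState, Topology

__all__ = [
    "BirthDeathSpec",
    "birth_death_sim",
    "markov_chain_series",
    "geometric_fixture",
]


@dataclass(frozen=True)
class BirthDeathSpec:
    """A 1D birth-death chain on sizes 1..n_max.

    ``birth_rates[m]`` / ``death_rates[m]`` are the up/down rates out of
    size m (index 0 unused).  Boundaries are reflecting: the death rate
    at 1 and the birth rate at n_max are forced to zero.
    """

    n_max: int
    birth_rates: tuple
    death_rates: tuple
    m0: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_max < 2:
            raise ValueError("n_max must be >= 2")
        if len(self.birth_rates) != self.n_max + 1 or len(self.death_rates) != self.n_max + 1:
            raise ValueError("rate arrays must have length n_max + 1 (index by size)")
        if any(r < 0 for r in self.birth_rates) or any(r < 0 for r in self.death_rates):
            raise ValueError("rates must be non-negative")
        if not 1 <= self.m0 <= self.n_max:
            raise ValueError("m0 must lie in [1, n_max]")

    def effective_rates(self) -> tuple[np.ndarray, np.ndarray]:
        lam = np.asarray(self.birth_rates, dtype=float).copy()
        mu = np.asarray(self.death_rates, dtype=float).copy()
        lam[self.n_max] = 0.0
        mu[1] = 0.0
        mu[0] = lam[0] = 0.0
        return lam, mu


def birth_death_sim(
    spec: BirthDeathSpec, duration: float, stride: float
) -> tuple[np.ndarray, np.ndarray]:
    """Gillespie trajectory of the birth-death chain, sampled on a grid.

    Returns ``(times, m)`` with ``times = 0, stride, 2*stride, ...`` up
    to ``duration`` and ``m`` the chain state at each grid time
    (value of the most recent event).  Deterministic given the seed.
    """
    if duration <= 0 or stride <= 0:
        raise ValueError("duration and stride must be positive")
    lam, mu = spec.effective_rates()
    rng = np.random.default_rng(spec.seed)
    grid = np.arange(0.0, duration + 0.5 * stride, stride)
    out = np.empty(len(grid), dtype=np.int64)
    m = spec.m0
    t = 0.0
    gi = 0
    while gi < len(grid):
        total = lam[m] + mu[m]
        t_next = t + (rng.exponential(1.0 / total) if total > 0 else np.inf)
        while gi < len(grid) and grid[gi] < t_next:
            out[gi] = m
            gi += 1
        if t_next > duration:
            break
        t = t_next
        m = m + 1 if rng.random() * total < lam[m] else m - 1
    out[gi:] = m
    return grid, out


def markov_chain_series(
    p_up: np.ndarray,
    p_down: np.ndarray,
    n_steps: int,
    m0: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Discrete-time +-1 random walk with per-state move probabilities.

    ``p_up[m]``/``p_down[m]`` are the probabilities of m -> m+1 / m-1 at
    each step (the remainder stays).  Reflecting at 1 and at
    ``len(p_up) - 1``.  Useful as a direct oracle for the transition
    probability matrix estimator.
    """
    top = len(p_up) - 1
    out = np.empty(n_steps, dtype=np.int64)
    m = m0
    u = rng.random(n_steps)
    for i in range(n_steps):
        out[i] = m
        up = p_up[m] if m < top else 0.0
        down = p_down[m] if m > 1 else 0.0
        if u[i] < up:
            m += 1
        elif u[i] < up + down:
            m -= 1
    return out


def geometric_fixture(kind: str, **params) -> tuple[SystemState, Topology]:
    """Deterministic configurations with analytically known structure.

    Kinds
    -----
    ``parallel-lattice``
        ``n_chains`` straight chains along z on an xy grid
        (``spacing`` nm apart): C_n = 1, one cluster when the spacing is
        below the cluster cutoff.
    ``random-gas``
        Well-separated chains with random orientations on a coarse grid:
        ``n_chains`` clusters of size 1 under any cutoff below the grid
        margin.
    ``boundary-spanning-cluster``
        Two chains in contact only across the periodic box face: one
        cluster under minimum-image clustering, two under naive
        distances.
    ``rod``
        A single collinear chain: b = R_g^2.
    ``cube``
        Eight beads on the vertices of a cube: b = 0 by symmetry.
    """
    if kind == "parallel-lattice":
        n_chains = params.get("n_chains", 10)
        length = params.get("chain_length", 8)
        spacing = params.get("spacing", 0.5)
        bond = params.get("bond_length", 0.35)
        side = int(np.ceil(np.sqrt(n_chains)))
        box = params.get("box", max(4.0, side * spacing + (length + 2) * bond + 3.0))
        coords = []
        for c in range(n_chains):
            gx, gy = divmod(c, side)
            x0 = 1.0 + gx * spacing
            y0 = 1.0 + gy * spacing
            for b in range(length):
                coords.append((x0, y0, 1.0 + b * bond))
        topo = Topology(n_chains, length)
        pos = np.asarray(coords)
        return SystemState(pos, np.zeros_like(pos), box), topo

    if kind == "random-gas":
        n_chains = params.get("n_chains", 72)
        length = params.get("chain_length", 8)
        bond = params.get("bond_length", 0.35)
        seed = params.get("seed", 0)
        margin = params.get("margin", 1.0)
        rng = np.random.default_rng(seed)
        cell = (length - 1) * bond + 2 * margin
        side = int(np.ceil(n_chains ** (1.0 / 3.0)))
        box = side * cell
        offsets = (np.arange(length) - 0.5 * (length - 1)) * bond
        coords = []
        for c in range(n_chains):
            gz, rem = divmod(c, side * side)
            gy, gx = divmod(rem, side)
            center = (np.array([gx, gy, gz]) + 0.5) * cell
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            coords.append(center[None, :] + offsets[:, None] * v[None, :])
        topo = Topology(n_chains, length)
        pos = np.concatenate(coords)
        return SystemState(pos, np.zeros_like(pos), box), topo

    if kind == "boundary-spanning-cluster":
        box = params.get("box", 10.0)
        length = params.get("chain_length", 8)
        bond = params.get("bond_length", 0.35)
        gap = params.get("gap", 0.3)
        # chain A ends just below the +x face; chain B continues across it
        ax = box - (length - 1) * bond - 0.05
        a = np.column_stack(
            [ax + np.arange(length) * bond, np.full(length, 2.0), np.full(length, 2.0)]
        )
        bx = a[-1, 0] + gap
        b = np.column_stack(
            [bx + np.arange(length) * bond, np.full(length, 2.0), np.full(length, 2.0)]
        )
        topo = Topology(2, length)
        pos = np.concatenate([a, b])
        return SystemState(pos, np.zeros_like(pos), box), topo

    if kind == "rod":
        n = params.get("n_beads", 8)
        spacing = params.get("spacing", 0.35)
        box = params.get("box", max(4.0, n * spacing + 4.0))
        pos = np.column_stack(
            [1.0 + np.arange(n) * spacing, np.full(n, 1.0), np.full(n, 1.0)]
        )
        topo = Topology(1, n)
        return SystemState(pos, np.zeros_like(pos), box), topo

    if kind == "cube":
        edge = params.get("edge", 1.0)
        box = params.get("box", 4.0 + 2 * edge)
        corners = np.array(
            [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)], dtype=float
        )
        pos = 1.0 + corners * edge
        topo = Topology(1, 8)
        return SystemState(pos, np.zeros_like(pos), box), topo

    raise ValueError(f"unknown fixture kind {kind!r}")
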