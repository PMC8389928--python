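"""Shared fixtures: small random systems and brute-force oracles.

The oracles here are deliberately independent re-implementations
(plain double loops, no k-d tree, no jit) used to cross-check the
production paths.
"""

from __future__ import annotations

import numpy as np
import pytest

from peptagg import ForceField, SystemSpec, SystemState, Topology, random_initial_config


@pytest.fixture
def ff() -> ForceField:
    return ForceField()


@pytest.fixture
def small_system(ff):
    """Five SA8 chains at a concentration high enough to interact."""
    spec = SystemSpec(n_chains=5, chain_length=8, c0=30.0, seed=42)
    return random_initial_config(spec, ff)


def brute_force_energy(pos: np.ndarray, box: float, topo: Topology, ff: ForceField):
    """All-pairs, no-neighbour-list energy/force oracle (pure python loops)."""
    n = len(pos)
    pos = pos % box
    forces = np.zeros((n, 3))
    energy = 0.0

    def mi(d):
        return d - box * np.round(d / box)

    for i, j in topo.bonds:
        d = mi(pos[i] - pos[j])
        r = np.linalg.norm(d)
        energy += 0.5 * ff.k_b * (r - ff.r0) ** 2
        f = -ff.k_b * (r - ff.r0) * d / r
        forces[i] += f
        forces[j] -= f

    for i, j, k in topo.angles:
        u = mi(pos[i] - pos[j])
        v = mi(pos[k] - pos[j])
        lu, lv = np.linalg.norm(u), np.linalg.norm(v)
        cth = float(np.clip(u @ v / (lu * lv), -1, 1))
        diff = cth - ff.cos_theta0
        energy += 0.5 * ff.k_theta * diff**2
        dvdcos = ff.k_theta * diff
        di = v / (lu * lv) - cth * u / lu**2
        dk = u / (lu * lv) - cth * v / lv**2
        forces[i] += -dvdcos * di
        forces[k] += -dvdcos * dk
        forces[j] -= -dvdcos * di + -dvdcos * dk

    shift = ff.lj_shift_energy
    for i in range(n - 1):
        for j in range(i + 1, n):
            if (
                topo.chain_ids[i] == topo.chain_ids[j]
                and abs(int(topo.index_in_chain[i]) - int(topo.index_in_chain[j]))
                <= ff.exclusion_separation
            ):
                continue
            d = mi(pos[i] - pos[j])
            r2 = float(d @ d)
            if r2 > ff.lj_cutoff**2:
                continue
            sr6 = (ff.sigma**2 / r2) ** 3
            energy += 4 * ff.epsilon * (sr6**2 - sr6) - shift
            fr = 24 * ff.epsilon * (2 * sr6**2 - sr6) / r2
            forces[i] += fr * d
            forces[j] -= fr * d
    return energy, forces


def brute_force_partition(pos: np.ndarray, box: float, topo: Topology, cutoff: float):
    """Single-linkage chain partition by all-pairs union-find (oracle)."""
    parent = list(range(topo.n_chains))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    pos = pos % box
    n = len(pos)
    for i in range(n - 1):
        for j in range(i + 1, n):
            ci, cj = int(topo.chain_ids[i]), int(topo.chain_ids[j])
            if ci == cj:
                continue
            d = pos[i] - pos[j]
            d -= box * np.round(d / box)
            if float(d @ d) <= cutoff**2:
                union(ci, cj)
    return frozenset(
        frozenset(c for c in range(topo.n_chains) if find(c) == root)
        for root in {find(c) for c in range(topo.n_chains)}
    )


def partition_from_labels(labels: np.ndarray) -> frozenset:
    return frozenset(
        frozenset(np.flatnonzero(labels == lab).tolist()) for lab in np.unique(labels)
    )
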