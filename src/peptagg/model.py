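"""Force field and energetics of the coarse-grained homopeptide model.

Peptides are linear chains of identical "superatom" beads, one bead per
residue.  The potential energy has three terms:

* a harmonic bond between consecutive beads,
  ``V_b(r) = 1/2 k_b (r - r0)^2``;
* a cosine-harmonic bending term on consecutive bead triplets,
  ``V_a(theta) = 1/2 k_theta (cos(theta) - cos(theta0))^2`` with
  ``theta0 = 180 deg``, so straight chains are the bending minimum and the
  form is regular (no ``1/sin`` singularity) at the minimum itself;
* a truncated and (by default) shifted 12-6 Lennard-Jones attraction
  between all non-excluded bead pairs,
  ``V_lj(r) = 4 eps ((sigma/r)^12 - (sigma/r)^6)``.

Units follow the conventional bio-simulation system: nm, ps, amu, kJ/mol,
K.  In these units kJ/mol == amu nm^2 ps^-2, so a force in kJ mol^-1 nm^-1
divided by a mass in amu is directly an acceleration in nm ps^-2.

The system lives in a cubic periodic box; all pair distances use the
minimum-image convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "KB",
    "AVOGADRO",
    "ForceField",
    "Topology",
    "SystemState",
    "InvalidGeometryError",
    "ConfigurationError",
    "bond_energy_force",
    "angle_energy_force",
    "lj_energy_force",
    "total_energy_forces",
    "minimum_image",
]

#: Boltzmann constant, kJ mol^-1 K^-1.
KB = 8.31446261815324e-3
#: Avogadro constant, mol^-1.
AVOGADRO = 6.02214076e23

_EXCLUSION_SEPARATION = {"bonds": 1, "bonds+angles": 2}


class InvalidGeometryError(ValueError):
    """A geometric argument (distance, angle) is outside its domain."""


class ConfigurationError(ValueError):
    """System/force-field combination violates a validity requirement."""


@dataclass(frozen=True)
class ForceField:
    """All interaction parameters of the bead-spring homopeptide model.

    Parameters
    ----------
    k_b : float
        Bond force constant, kJ mol^-1 nm^-2.
    r0 : float
        Equilibrium bond length, nm.
    k_theta : float
        Bending force constant, kJ/mol.  The study grid spans 10-1000.
    theta0 : float
        Equilibrium bond angle, degrees (180 = straight chain).
    epsilon : float
        Lennard-Jones well depth, kJ/mol.  The study grid spans 1.3-2.0.
    sigma : float
        Lennard-Jones zero-crossing distance, nm.
    lj_cutoff : float
        Nonbonded cutoff, nm.  Must lie beyond the LJ minimum.
    shift_lj : bool
        If true, the LJ energy is shifted so it vanishes continuously at
        the cutoff (forces are unaffected).
    exclusion_policy : str
        Which bonded neighbours are excluded from LJ: ``"bonds"``
        (directly bonded 1-2 pairs only, the default) or
        ``"bonds+angles"`` (1-2 and 1-3 pairs).
    """

    k_b: float = 1250.0
    r0: float = 0.35
    k_theta: float = 400.0
    theta0: float = 180.0
    epsilon: float = 1.5
    sigma: float = 0.47
    lj_cutoff: float = 1.2
    shift_lj: bool = True
    exclusion_policy: str = "bonds"

    def __post_init__(self) -> None:
        if self.k_b <= 0:
            raise ValueError("k_b must be positive")
        if self.k_theta < 0:
            raise ValueError("k_theta must be non-negative")
        if self.epsilon <= 0 or self.sigma <= 0 or self.r0 <= 0:
            raise ValueError("epsilon, sigma and r0 must be positive")
        if self.lj_cutoff <= 2.0 ** (1.0 / 6.0) * self.sigma:
            raise ValueError(
                "lj_cutoff must lie beyond the LJ minimum at 2^(1/6) sigma"
            )
        if self.exclusion_policy not in _EXCLUSION_SEPARATION:
            raise ValueError(
                f"unknown exclusion_policy {self.exclusion_policy!r}; "
                f"expected one of {sorted(_EXCLUSION_SEPARATION)}"
            )

    @property
    def cos_theta0(self) -> float:
        return float(np.cos(np.deg2rad(self.theta0)))

    @property
    def exclusion_separation(self) -> int:
        """Largest intra-chain index separation excluded from LJ."""
        return _EXCLUSION_SEPARATION[self.exclusion_policy]

    @property
    def lj_shift_energy(self) -> float:
        """Energy subtracted from every in-range LJ pair (0 if unshifted)."""
        if not self.shift_lj:
            return 0.0
        sr6 = (self.sigma / self.lj_cutoff) ** 6
        return 4.0 * self.epsilon * (sr6 * sr6 - sr6)

    def replace(self, **changes) -> "ForceField":
        return replace(self, **changes)


@dataclass(frozen=True)
class Topology:
    """Bead bookkeeping for ``n_chains`` identical linear chains.

    Bead ``i`` belongs to chain ``i // chain_length`` at intra-chain
    position ``i % chain_length`` — a bijection between the flat bead
    index and (chain, position).
    """

    n_chains: int
    chain_length: int
    mass: float = 72.0

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.chain_length < 1:
            raise ValueError("n_chains and chain_length must be >= 1")
        if self.mass <= 0:
            raise ValueError("mass must be positive")

    @property
    def n_beads(self) -> int:
        return self.n_chains * self.chain_length

    @cached_property
    def chain_ids(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_chains), self.chain_length)

    @cached_property
    def index_in_chain(self) -> np.ndarray:
        return np.tile(np.arange(self.chain_length), self.n_chains)

    @cached_property
    def bonds(self) -> np.ndarray:
        """(n_bonds, 2) array of bonded bead-index pairs."""
        if self.chain_length < 2:
            return np.empty((0, 2), dtype=np.int64)
        first = np.arange(self.n_beads).reshape(self.n_chains, self.chain_length)
        i = first[:, :-1].ravel()
        return np.column_stack([i, i + 1]).astype(np.int64)

    @cached_property
    def angles(self) -> np.ndarray:
        """(n_angles, 3) array of consecutive bead triplets (i, j, k)."""
        if self.chain_length < 3:
            return np.empty((0, 3), dtype=np.int64)
        first = np.arange(self.n_beads).reshape(self.n_chains, self.chain_length)
        i = first[:, :-2].ravel()
        return np.column_stack([i, i + 1, i + 2]).astype(np.int64)

    def chain_slice(self, chain: int) -> slice:
        start = chain * self.chain_length
        return slice(start, start + self.chain_length)


@dataclass
class SystemState:
    """Positions/velocities of every bead plus the cubic box and clock.

    Positions are stored wrapped into ``[0, box)`` in each dimension;
    analysis code unwraps as needed.  Velocities are nm/ps and, during
    leap-frog propagation, refer to the half-step ``t - dt/2``.
    """

    positions: np.ndarray
    velocities: np.ndarray
    box: float
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_beads, 3)")
        if self.velocities.shape != self.positions.shape:
            raise ValueError("velocities must match positions in shape")
        if self.box <= 0:
            raise ValueError("box must be positive")
        self.positions %= self.box

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "SystemState":
        return SystemState(
            self.positions.copy(), self.velocities.copy(), self.box, self.time
        )


def minimum_image(d: np.ndarray, box: float) -> np.ndarray:
    """Map displacement vectors to their nearest periodic image."""
    return d - box * np.round(d / box)


def bond_energy_force(r, ff: ForceField):
    """Harmonic bond energy and scalar force at separation ``r`` (nm).

    Returns ``(energy, force)`` with ``force = -dV/dr``; positive force
    pushes the pair apart.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise InvalidGeometryError("bond length must be positive")
    dr = r - ff.r0
    energy = 0.5 * ff.k_b * dr * dr
    force = -ff.k_b * dr
    if energy.ndim == 0:
        return float(energy), float(force)
    return energy, force


def angle_energy_force(theta, ff: ForceField):
    """Cosine-harmonic bending energy and torque at angle ``theta`` (deg).

    Returns ``(energy, torque)`` where ``torque = -dV/dtheta`` in
    kJ mol^-1 rad^-1.  In the full force evaluation the equivalent
    Cartesian forces on the (i, j, k) triplet sum to zero.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any((theta < 0) | (theta > 180)):
        raise InvalidGeometryError("angle must lie in [0, 180] degrees")
    th = np.deg2rad(theta)
    diff = np.cos(th) - ff.cos_theta0
    energy = 0.5 * ff.k_theta * diff * diff
    torque = ff.k_theta * diff * np.sin(th)
    if energy.ndim == 0:
        return float(energy), float(torque)
    return energy, torque


def lj_energy_force(r, ff: ForceField, *, shifted: bool | None = None):
    """12-6 Lennard-Jones energy and scalar force at separation ``r`` (nm).

    Energy and force are exactly zero beyond ``ff.lj_cutoff``.  With
    ``shifted`` true (default: the force field's own setting) the energy
    is shifted to vanish continuously at the cutoff; the force is never
    shifted.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise InvalidGeometryError("LJ separation must be positive (r = 0 is singular)")
    if shifted is None:
        shifted = ff.shift_lj
    sr6 = (ff.sigma / r) ** 6
    energy = 4.0 * ff.epsilon * (sr6 * sr6 - sr6)
    force = 24.0 * ff.epsilon * (2.0 * sr6 * sr6 - sr6) / r
    if shifted:
        src6 = (ff.sigma / ff.lj_cutoff) ** 6
        energy = energy - 4.0 * ff.epsilon * (src6 * src6 - src6)
    outside = r > ff.lj_cutoff
    energy = np.where(outside, 0.0, energy)
    force = np.where(outside, 0.0, force)
    if energy.ndim == 0:
        return float(energy), float(force)
    return energy, force


def _validate_system(state: SystemState, topo: Topology, ff: ForceField) -> None:
    if state.positions.shape[0] != topo.n_beads:
        raise ValueError(
            f"state has {state.positions.shape[0]} beads, topology expects "
            f"{topo.n_beads}"
        )
    if state.box < 2.0 * ff.lj_cutoff:
        raise ConfigurationError(
            f"box ({state.box:g} nm) must be at least twice the LJ cutoff "
            f"({ff.lj_cutoff:g} nm) for the minimum-image convention"
        )


def total_energy_forces(
    state: SystemState,
    topo: Topology,
    ff: ForceField,
    *,
    backend: str = "numba",
):
    """Total potential energy and per-bead forces.

    Sums all bond terms, all angle terms and every non-excluded
    nonbonded pair within the cutoff under the minimum-image convention.
    Forces are exact negative gradients of the energy.

    Parameters
    ----------
    backend : {"numba", "numpy"}
        "numba" uses the jit-compiled all-pairs kernel (production path);
        "numpy" is the vectorised reference path whose neighbour search
        goes through a periodic k-d tree.  The two agree to roundoff.
    """
    _validate_system(state, topo, ff)
    pos = state.positions % state.box
    if backend == "numba":
        from ._kernels import energy_forces_kernel

        energy, forces = energy_forces_kernel(
            pos,
            state.box,
            topo.chain_ids,
            topo.index_in_chain,
            topo.bonds,
            topo.angles,
            ff.k_b,
            ff.r0,
            ff.k_theta,
            ff.cos_theta0,
            ff.epsilon,
            ff.sigma,
            ff.lj_cutoff,
            ff.lj_shift_energy,
            ff.exclusion_separation,
        )
        return float(energy), forces
    if backend == "numpy":
        return _energy_forces_numpy(pos, state.box, topo, ff)
    raise ValueError(f"unknown backend {backend!r}")


def _energy_forces_numpy(pos: np.ndarray, box: float, topo: Topology, ff: ForceField):
    """Vectorised reference evaluation (periodic k-d tree neighbour search)."""
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    energy = 0.0

    bonds = topo.bonds
    if len(bonds):
        d = minimum_image(pos[bonds[:, 0]] - pos[bonds[:, 1]], box)
        r = np.linalg.norm(d, axis=1)
        e, f = bond_energy_force(r, ff)
        energy += float(np.sum(e))
        fv = (np.atleast_1d(f) / r)[:, None] * d
        np.add.at(forces, bonds[:, 0], fv)
        np.add.at(forces, bonds[:, 1], -fv)

    angles = topo.angles
    if len(angles) and ff.k_theta > 0:
        u = minimum_image(pos[angles[:, 0]] - pos[angles[:, 1]], box)
        v = minimum_image(pos[angles[:, 2]] - pos[angles[:, 1]], box)
        lu = np.linalg.norm(u, axis=1)
        lv = np.linalg.norm(v, axis=1)
        cth = np.clip(np.sum(u * v, axis=1) / (lu * lv), -1.0, 1.0)
        diff = cth - ff.cos_theta0
        energy += float(0.5 * ff.k_theta * np.sum(diff * diff))
        dvdcos = (ff.k_theta * diff)[:, None]
        dcos_di = v / (lu * lv)[:, None] - (cth / lu**2)[:, None] * u
        dcos_dk = u / (lu * lv)[:, None] - (cth / lv**2)[:, None] * v
        fi = -dvdcos * dcos_di
        fk = -dvdcos * dcos_dk
        np.add.at(forces, angles[:, 0], fi)
        np.add.at(forces, angles[:, 2], fk)
        np.add.at(forces, angles[:, 1], -(fi + fk))

    tree = cKDTree(pos, boxsize=box)
    pairs = tree.query_pairs(ff.lj_cutoff, output_type="ndarray")
    if len(pairs):
        ci = topo.chain_ids[pairs[:, 0]]
        cj = topo.chain_ids[pairs[:, 1]]
        sep = np.abs(
            topo.index_in_chain[pairs[:, 0]] - topo.index_in_chain[pairs[:, 1]]
        )
        keep = (ci != cj) | (sep > ff.exclusion_separation)
        pairs = pairs[keep]
    if len(pairs):
        d = minimum_image(pos[pairs[:, 0]] - pos[pairs[:, 1]], box)
        r2 = np.sum(d * d, axis=1)
        inside = r2 <= ff.lj_cutoff**2
        pairs, d, r2 = pairs[inside], d[inside], r2[inside]
        sr2 = ff.sigma**2 / r2
        sr6 = sr2 * sr2 * sr2
        sr12 = sr6 * sr6
        energy += float(
            np.sum(4.0 * ff.epsilon * (sr12 - sr6) - ff.lj_shift_energy)
        )
        fr = (24.0 * ff.epsilon * (2.0 * sr12 - sr6) / r2)[:, None] * d
        np.add.at(forces, pairs[:, 0], fr)
        np.add.at(forces, pairs[:, 1], -fr)

    return energy, forces
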