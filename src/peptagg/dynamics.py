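"""Leap-frog stochastic (Langevin) dynamics and kinetic observables.

The integrator is an impulse leap-frog Langevin scheme: a deterministic
leap-frog velocity kick followed by an exact Ornstein-Uhlenbeck velocity
update,

    v(t+dt/2) = a * [v(t-dt/2) + (dt/m) F(t)] + sqrt(1-a^2) sqrt(kB T/m) xi
    x(t+dt)   = x(t) + dt v(t+dt/2),      a = exp(-dt / tau_f)

with ``xi`` independent standard normals.  The friction enters through
the velocity-relaxation time ``tau_f`` (gamma_i = m_i / tau_f).  The
solvent is implicit: friction plus matched noise act as the thermostat.
In the limit ``tau_f -> inf`` the scheme reduces to deterministic
leap-frog; for a free particle the stationary velocity distribution is
exactly Maxwell-Boltzmann at the set temperature for any dt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    KB,
    ForceField,
    SystemState,
    Topology,
    _energy_forces_numpy,
    _validate_system,
    total_energy_forces,
)

__all__ = [
    "IntegratorParams",
    "IntegrationBlowUpError",
    "SimulationResult",
    "sd_leapfrog_step",
    "simulate",
    "kinetic_temperature",
    "maxwell_boltzmann_velocities",
    "measure_diffusion",
    "DiffusionResult",
]


class IntegrationBlowUpError(RuntimeError):
    """Positions or velocities became non-finite during integration."""


@dataclass(frozen=True)
class IntegratorParams:
    """Stochastic-dynamics settings.

    ``dt`` is the timestep in ps (default 0.025, i.e. 25 fs);
    ``temperature`` the thermostat temperature in K (default 303);
    ``tau_f`` the inverse friction coefficient in ps, i.e. the velocity
    relaxation time (default 0.17; ``inf`` gives frictionless,
    deterministic leap-frog).  ``seed`` seeds the noise stream.
    """

    dt: float = 0.025
    temperature: float = 303.0
    tau_f: float = 0.17
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        if not self.tau_f > 0:
            raise ValueError("tau_f must be positive (inf = frictionless)")

    def ou_coefficients(self, mass: float) -> tuple[float, float]:
        """(a, c): velocity decay factor and noise amplitude per step."""
        if math.isinf(self.tau_f):
            return 1.0, 0.0
        a = math.exp(-self.dt / self.tau_f)
        c = math.sqrt((1.0 - a * a) * KB * self.temperature / mass)
        return a, c


def maxwell_boltzmann_velocities(
    n_beads: int, mass: float, temperature: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw (n_beads, 3) velocities from Maxwell-Boltzmann at ``temperature``."""
    return rng.normal(0.0, math.sqrt(KB * temperature / mass), size=(n_beads, 3))


def kinetic_temperature(state: SystemState, topo: Topology) -> float:
    """Instantaneous kinetic temperature T = sum(m v^2) / (3 N kB)."""
    v2 = float(np.sum(state.velocities**2))
    return topo.mass * v2 / (3.0 * state.n_beads * KB)


def sd_leapfrog_step(
    state: SystemState,
    topo: Topology,
    ff: ForceField,
    ip: IntegratorParams,
    rng: np.random.Generator,
    *,
    forces: np.ndarray | None = None,
    backend: str = "numba",
) -> SystemState:
    """Advance the system by one stochastic leap-frog step.

    ``state.velocities`` are interpreted as the half-step velocities
    v(t - dt/2); the returned state carries v(t + dt/2) and x(t + dt).
    Pass ``forces`` (at the current positions) to avoid recomputation.
    """
    if forces is None:
        _, forces = total_energy_forces(state, topo, ff, backend=backend)
    a, c = ip.ou_coefficients(topo.mass)
    vel = a * (state.velocities + (ip.dt / topo.mass) * forces)
    if c > 0.0:
        vel = vel + c * rng.standard_normal(state.velocities.shape)
    pos = state.positions + ip.dt * vel
    if not np.all(np.isfinite(pos)):
        raise IntegrationBlowUpError(
            f"non-finite positions after step at t = {state.time:g} ps"
        )
    return SystemState(pos, vel, state.box, state.time + ip.dt)


@dataclass
class SimulationResult:
    """Stored frames and logs of a propagation run."""

    state: SystemState
    times: np.ndarray
    positions: np.ndarray  # (n_frames, n_beads, 3), wrapped
    log: pd.DataFrame  # columns: time, potential, kinetic, temperature
    unwrapped: np.ndarray | None = None


def simulate(
    state: SystemState,
    topo: Topology,
    ff: ForceField,
    ip: IntegratorParams,
    n_steps: int,
    *,
    traj_stride: int = 100,
    log_stride: int = 100,
    rng: np.random.Generator | None = None,
    store_unwrapped: bool = False,
    backend: str = "numba",
) -> SimulationResult:
    """Propagate ``n_steps`` stochastic leap-frog steps.

    Frame 0 (the input state) is always stored; thereafter every
    ``traj_stride``-th step.  Potential energy, kinetic energy (the
    average of the two half-step kinetic energies adjacent to each full
    step, the usual leap-frog convention) and kinetic temperature are
    logged every ``log_stride`` steps.  Identical seed and inputs give
    bit-identical trajectories.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be non-negative")
    if traj_stride < 1 or log_stride < 1:
        raise ValueError("strides must be >= 1")
    if rng is None:
        rng = np.random.default_rng(ip.seed)

    box = state.box
    mass = topo.mass
    n = topo.n_beads
    pos = state.positions % box
    vel = state.velocities.copy()
    unwr = pos.copy() if store_unwrapped else None
    a, c = ip.ou_coefficients(mass)
    dt = ip.dt

    # resolve the force evaluator once; the hot loop avoids any per-step
    # object construction or revalidation
    _validate_system(state, topo, ff)
    if backend == "numba":
        from ._kernels import energy_forces_kernel

        ff_args = (
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

        def eval_forces(p):
            return energy_forces_kernel(p, box, *ff_args)

    elif backend == "numpy":

        def eval_forces(p):
            return _energy_forces_numpy(p, box, topo, ff)

    else:
        raise ValueError(f"unknown backend {backend!r}")

    energy, forces = eval_forces(pos)

    frames = [pos.copy()]
    frame_times = [state.time]
    unwr_frames = [unwr.copy()] if store_unwrapped else None
    log_rows = []

    def log_point(step: int, t: float, e_pot: float, ke: float) -> None:
        if not (np.isfinite(e_pot) and np.isfinite(ke)):
            raise IntegrationBlowUpError(
                f"non-finite energy at step {step} (t = {t:g} ps)"
            )
        log_rows.append((t, e_pot, ke, 2.0 * ke / (3.0 * n * KB)))

    t = state.time
    for step in range(1, n_steps + 1):
        # vel holds v(t - dt/2) and energy/forces refer to x(t)
        vel_new = a * (vel + (dt / mass) * forces)
        if c > 0.0:
            vel_new += c * rng.standard_normal((n, 3))
        if (step - 1) % log_stride == 0:
            # leap-frog convention: KE(t) = mean of the adjacent
            # half-step kinetic energies, paired with V(x(t))
            ke = 0.25 * mass * float(np.sum(vel * vel) + np.sum(vel_new * vel_new))
            log_point(step - 1, t, energy, ke)
        vel = vel_new
        disp = dt * vel
        pos += disp
        if store_unwrapped:
            unwr += disp
        pos %= box
        t = state.time + step * dt
        energy, forces = eval_forces(pos)
        if step % traj_stride == 0:
            frames.append(pos.copy())
            frame_times.append(t)
            if store_unwrapped:
                unwr_frames.append(unwr.copy())
    # final point: only the trailing half-step velocity is available
    log_point(n_steps, t, energy, 0.5 * mass * float(np.sum(vel * vel)))

    final = SystemState(pos.copy(), vel.copy(), box, t)
    log = pd.DataFrame(
        log_rows, columns=["time", "potential", "kinetic", "temperature"]
    ).drop_duplicates(subset="time")
    return SimulationResult(
        state=final,
        times=np.asarray(frame_times),
        positions=np.asarray(frames),
        log=log,
        unwrapped=np.asarray(unwr_frames) if store_unwrapped else None,
    )


@dataclass
class DiffusionResult:
    D: float  # nm^2 / ps
    intercept: float
    lag_times: np.ndarray
    msd: np.ndarray


def measure_diffusion(
    times: np.ndarray,
    positions: np.ndarray,
    *,
    fit_start: float | None = None,
    fit_end: float | None = None,
    n_lags: int = 40,
) -> DiffusionResult:
    """Diffusion coefficient from the long-time MSD slope.

    ``positions`` must be unwrapped (image-corrected) coordinates of
    shape (n_frames, 3) for one particle or (n_frames, n_particles, 3)
    for an ensemble; the MSD is averaged over particles and sliding time
    origins, then fitted as ``MSD = 6 D t + b`` over
    ``[fit_start, fit_end]`` (defaults: 10 %-50 % of the trajectory
    length, inside the diffusive regime for lags well beyond tau_f).
    """
    times = np.asarray(times, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if positions.ndim == 2:
        positions = positions[:, None, :]
    n_frames = positions.shape[0]
    if n_frames != len(times) or n_frames < 4:
        raise ValueError("trajectory too short for the MSD fit window")
    total = times[-1] - times[0]
    if fit_start is None:
        fit_start = 0.1 * total
    if fit_end is None:
        fit_end = 0.5 * total
    dt_frame = total / (n_frames - 1)
    k_min = max(1, int(round(fit_start / dt_frame)))
    k_max = min(n_frames - 2, int(round(fit_end / dt_frame)))
    if k_max <= k_min:
        raise ValueError("trajectory too short for the MSD fit window")
    lags = np.unique(np.linspace(k_min, k_max, n_lags).astype(int))
    msd = np.empty(len(lags))
    for idx, k in enumerate(lags):
        d = positions[k:] - positions[:-k]
        msd[idx] = float(np.mean(np.sum(d * d, axis=-1)))
    lag_times = lags * dt_frame
    slope, intercept = np.polyfit(lag_times, msd, 1)
    return DiffusionResult(
        D=slope / 6.0, intercept=intercept, lag_times=lag_times, msd=msd
    )
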