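"""File formats and run configuration.

Trajectories are written as extended XYZ (box in the comment line via
the ``Lattice`` key) and as fixed-column GRO frames; time series and
tables go to CSV, estimates and run metadata to JSON.  A run is fully
reproducible from its YAML config plus seed: every physical key in the
config carries its unit in the key name (nm, ps, kJ/mol, K, amu — the
unit system used throughout the package).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .builder import SystemSpec
from .dynamics import IntegratorParams
from .model import ForceField, SystemState, Topology

__all__ = [
    "TrajectoryParseError",
    "write_xyz",
    "read_xyz",
    "write_gro",
    "read_gro",
    "RunSettings",
    "AnalysisSettings",
    "RunConfig",
    "load_config",
    "save_config",
]


class TrajectoryParseError(ValueError):
    """Malformed trajectory file; the message names the offending line."""


# ---------------------------------------------------------------------------
# extended XYZ


def write_xyz(
    path: str | Path,
    positions: np.ndarray,
    box: float,
    times: np.ndarray | None = None,
    species: str = "CA",
    mode: str = "w",
) -> None:
    """Write frames in extended-XYZ format (cubic box on the comment line).

    ``positions`` is (n_frames, n_beads, 3) or a single (n_beads, 3)
    frame.  An empty trajectory writes an empty file.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim == 2:
        positions = positions[None]
    if times is None:
        times = np.zeros(len(positions))
    with open(path, mode) as fh:
        for frame, t in zip(positions, times):
            fh.write(f"{len(frame)}\n")
            fh.write(
                f'Lattice="{box:.6f} 0.0 0.0 0.0 {box:.6f} 0.0 0.0 0.0 '
                f'{box:.6f}" Properties=species:S:1:pos:R:3 Time={t:.6f}\n'
            )
            for x, y, z in frame:
                fh.write(f"{species} {x:.9f} {y:.9f} {z:.9f}\n")


def read_xyz(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read an extended-XYZ trajectory.

    Returns ``(positions, boxes, times)`` with shapes (F, N, 3), (F,),
    (F,).  An empty file returns empty arrays.
    """
    lines = Path(path).read_text().splitlines()
    frames, boxes, times = [], [], []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise TrajectoryParseError(
                f"{path}: line {i + 1}: expected atom count, got {lines[i]!r}"
            ) from exc
        if i + 1 + n >= len(lines) + 1 and n > 0 and i + 1 + n > len(lines):
            raise TrajectoryParseError(
                f"{path}: line {i + 1}: frame of {n} atoms truncated"
            )
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        box = np.nan
        t = np.nan
        if "Lattice=" in comment:
            try:
                lattice = comment.split('Lattice="')[1].split('"')[0].split()
                box = float(lattice[0])
            except (IndexError, ValueError) as exc:
                raise TrajectoryParseError(
                    f"{path}: line {i + 2}: malformed Lattice entry"
                ) from exc
        if "Time=" in comment:
            try:
                t = float(comment.split("Time=")[1].split()[0])
            except (IndexError, ValueError) as exc:
                raise TrajectoryParseError(
                    f"{path}: line {i + 2}: malformed Time entry"
                ) from exc
        coords = np.empty((n, 3))
        for k in range(n):
            parts = lines[i + 2 + k].split()
            if len(parts) < 4:
                raise TrajectoryParseError(
                    f"{path}: line {i + 3 + k}: expected 'species x y z'"
                )
            coords[k] = [float(p) for p in parts[1:4]]
        frames.append(coords)
        boxes.append(box)
        times.append(t)
        i += 2 + n
    if not frames:
        return np.empty((0, 0, 3)), np.empty(0), np.empty(0)
    return np.asarray(frames), np.asarray(boxes), np.asarray(times)


# ---------------------------------------------------------------------------
# GRO (fixed-column)


def write_gro(
    path: str | Path,
    positions: np.ndarray,
    topo: Topology,
    box: float,
    velocities: np.ndarray | None = None,
    title: str = "coarse-grained homopeptide system",
) -> None:
    """Write one frame in GRO fixed-column format (nm, nm/ps).

    Each chain is a residue named ``PEP``; beads are named ``CA``.
    """
    positions = np.asarray(positions, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"{title}\n{len(positions):5d}\n")
        for i, xyz in enumerate(positions):
            resid = (topo.chain_ids[i] % 100000) + 1
            atnum = (i % 100000) + 1
            line = f"{resid:5d}{'PEP':<5s}{'CA':>5s}{atnum:5d}" + "".join(
                f"{c:8.3f}" for c in xyz
            )
            if velocities is not None:
                line += "".join(f"{v:8.4f}" for v in velocities[i])
            fh.write(line + "\n")
        fh.write(f"{box:10.5f}{box:10.5f}{box:10.5f}\n")


def read_gro(path: str | Path) -> tuple[np.ndarray, np.ndarray | None, float]:
    """Read a GRO frame; returns ``(positions, velocities_or_None, box)``."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise TrajectoryParseError(f"{path}: line 1: file too short for GRO")
    try:
        n = int(lines[1].strip())
    except ValueError as exc:
        raise TrajectoryParseError(
            f"{path}: line 2: expected atom count, got {lines[1]!r}"
        ) from exc
    if len(lines) < n + 3:
        raise TrajectoryParseError(f"{path}: line 3: truncated GRO frame")
    pos = np.empty((n, 3))
    vel = np.empty((n, 3))
    has_vel = len(lines[2].rstrip("\n")) >= 68
    for k in range(n):
        line = lines[2 + k]
        try:
            pos[k] = [float(line[20 + 8 * j : 28 + 8 * j]) for j in range(3)]
            if has_vel:
                vel[k] = [float(line[44 + 8 * j : 52 + 8 * j]) for j in range(3)]
        except (ValueError, IndexError) as exc:
            raise TrajectoryParseError(
                f"{path}: line {3 + k}: malformed GRO atom line"
            ) from exc
    box = float(lines[2 + n].split()[0])
    return pos, (vel if has_vel else None), box


# ---------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class RunSettings:
    n_steps: int = 200_000
    traj_stride: int = 1000
    log_stride: int = 1000


@dataclass(frozen=True)
class AnalysisSettings:
    cluster_cutoff: float = 0.55  # nm
    eq_fraction: float = 0.2
    min_lag_fraction: float = 0.05
    size_fraction: float = 0.25
    min_size: int = 4


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run: force field + integrator +
    system spec + run/analysis settings.  Serialisable to a YAML file
    whose keys carry explicit units."""

    forcefield: ForceField = field(default_factory=ForceField)
    integrator: IntegratorParams = field(default_factory=IntegratorParams)
    system: SystemSpec = field(default_factory=SystemSpec)
    run: RunSettings = field(default_factory=RunSettings)
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)

    def to_dict(self) -> dict:
        ff, ip, sp = self.forcefield, self.integrator, self.system
        return {
            "forcefield": {
                "k_b_kJ_per_mol_nm2": ff.k_b,
                "r0_nm": ff.r0,
                "k_theta_kJ_per_mol": ff.k_theta,
                "theta0_deg": ff.theta0,
                "epsilon_kJ_per_mol": ff.epsilon,
                "sigma_nm": ff.sigma,
                "lj_cutoff_nm": ff.lj_cutoff,
                "shift_lj": ff.shift_lj,
                "exclusion_policy": ff.exclusion_policy,
            },
            "integrator": {
                "dt_ps": ip.dt,
                "temperature_K": ip.temperature,
                "tau_f_ps": ip.tau_f,
                "seed": ip.seed,
            },
            "system": {
                "n_chains": sp.n_chains,
                "chain_length": sp.chain_length,
                "c0_mM": sp.c0,
                "min_sep_nm": sp.min_sep,
                "seed": sp.seed,
                "mass_amu": sp.mass,
            },
            "run": asdict(self.run),
            "analysis": {
                "cluster_cutoff_nm": self.analysis.cluster_cutoff,
                "eq_fraction": self.analysis.eq_fraction,
                "min_lag_fraction": self.analysis.min_lag_fraction,
                "size_fraction": self.analysis.size_fraction,
                "min_size": self.analysis.min_size,
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        ffd = data.get("forcefield", {})
        ipd = data.get("integrator", {})
        spd = data.get("system", {})
        rnd = data.get("run", {})
        and_ = data.get("analysis", {})
        ff = ForceField(
            k_b=ffd.get("k_b_kJ_per_mol_nm2", 1250.0),
            r0=ffd.get("r0_nm", 0.35),
            k_theta=ffd.get("k_theta_kJ_per_mol", 400.0),
            theta0=ffd.get("theta0_deg", 180.0),
            epsilon=ffd.get("epsilon_kJ_per_mol", 1.5),
            sigma=ffd.get("sigma_nm", 0.47),
            lj_cutoff=ffd.get("lj_cutoff_nm", 1.2),
            shift_lj=ffd.get("shift_lj", True),
            exclusion_policy=ffd.get("exclusion_policy", "bonds"),
        )
        tau = ipd.get("tau_f_ps", 0.17)
        ip = IntegratorParams(
            dt=ipd.get("dt_ps", 0.025),
            temperature=ipd.get("temperature_K", 303.0),
            tau_f=float("inf") if tau in ("inf", None) else float(tau),
            seed=ipd.get("seed", 0),
        )
        sp = SystemSpec(
            n_chains=spd.get("n_chains", 72),
            chain_length=spd.get("chain_length", 8),
            c0=spd.get("c0_mM", 2.8),
            min_sep=spd.get("min_sep_nm", 0.6),
            seed=spd.get("seed", 0),
            mass=spd.get("mass_amu", 72.0),
        )
        run = RunSettings(
            n_steps=rnd.get("n_steps", 200_000),
            traj_stride=rnd.get("traj_stride", 1000),
            log_stride=rnd.get("log_stride", 1000),
        )
        ana = AnalysisSettings(
            cluster_cutoff=and_.get("cluster_cutoff_nm", 0.55),
            eq_fraction=and_.get("eq_fraction", 0.2),
            min_lag_fraction=and_.get("min_lag_fraction", 0.05),
            size_fraction=and_.get("size_fraction", 0.25),
            min_size=and_.get("min_size", 4),
        )
        return cls(ff, ip, sp, run, ana)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    data = config.to_dict()
    if np.isinf(config.integrator.tau_f):
        data["integrator"]["tau_f_ps"] = "inf"
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def write_metadata(path: str | Path, config: RunConfig, extra: dict | None = None) -> None:
    """Write the full reproduction record (config + package version)."""
    from . import __version__

    data = config.to_dict()
    if np.isinf(config.integrator.tau_f):
        data["integrator"]["tau_f_ps"] = "inf"
    payload = {"package_version": __version__, "config": data}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))
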