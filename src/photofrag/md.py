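"""Time propagation: velocity Verlet, velocity-rescaling thermostat,
NVE/NVT drivers and the total-energy conservation filter.

All temperature bookkeeping uses the vibrational degree-of-freedom count
3N − 6 (translations and rotations excluded), the same convention used by
the ionization module's thermal-energy correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .chem import (EV_TO_KE, K_BOLTZMANN_EV, KE_TO_EV, MolecularSystem,
                   read_xyz, write_xyz)
from .toy_pes import PES

__all__ = [
    "Trajectory",
    "trajectory_from_xyz",
    "velocity_verlet_step",
    "rescale_velocities",
    "instantaneous_temperature",
    "propagate_nvt",
    "propagate_nve",
    "energy_conservation_filter",
]


@dataclass
class Trajectory:
    """Stored frames of one constant-energy run plus its total-energy trace."""

    times: np.ndarray  # fs, strictly increasing, constant spacing
    positions: np.ndarray  # (n_frames, N, 3) Å
    velocities: np.ndarray  # (n_frames, N, 3) Å/fs
    energies: np.ndarray  # total energy (eV) at each stored frame
    symbols: list[str]
    masses: np.ndarray
    metadata: dict = field(default_factory=dict)
    aborted: bool = False  # non-finite energy encountered during propagation

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def frame(self, k: int) -> MolecularSystem:
        return MolecularSystem(self.symbols, self.positions[k],
                               self.velocities[k], self.masses)

    def to_xyz(self, path: str | Path, write_velocities: bool = True) -> None:
        frames = []
        for k in range(self.n_frames):
            meta = {"time_fs": f"{self.times[k]:.3f}",
                    "E_tot_eV": f"{self.energies[k]:.8f}"}
            meta.update({k2: v for k2, v in self.metadata.items()
                         if isinstance(v, (int, float, str))})
            frames.append((self.frame(k), meta))
        write_xyz(frames, path, write_velocities=write_velocities)


def trajectory_from_xyz(path: str | Path) -> Trajectory:
    """Rebuild a :class:`Trajectory` from a multi-frame extended-XYZ file
    written by :meth:`Trajectory.to_xyz`."""
    frames = read_xyz(path)
    if not frames:
        raise ValueError(f"no frames in {path}")
    times, xs, vs, es = [], [], [], []
    meta: dict = {}
    for system, fmeta in frames:
        times.append(float(fmeta.get("time_fs", len(times))))
        xs.append(system.positions)
        vs.append(system.velocities)
        es.append(float(fmeta.get("E_tot_eV", 0.0)))
        for key, val in fmeta.items():
            if key not in ("time_fs", "E_tot_eV"):
                meta.setdefault(key, val)
    first = frames[0][0]
    return Trajectory(np.array(times), np.array(xs), np.array(vs),
                      np.array(es), list(first.symbols), first.masses.copy(),
                      metadata=meta)


def _dof(n_atoms: int) -> int:
    return max(3 * n_atoms - 6, 1)


def instantaneous_temperature(system: MolecularSystem) -> float:
    """Kinetic temperature in K under the 3N − 6 convention."""
    v2 = np.einsum("ij,ij->i", system.velocities, system.velocities)
    ke = 0.5 * float(np.dot(system.masses, v2)) * KE_TO_EV
    return 2.0 * ke / (_dof(system.n_atoms) * K_BOLTZMANN_EV)


def velocity_verlet_step(
    system: MolecularSystem, pes: PES, dt: float,
    gradient: np.ndarray | None = None,
) -> tuple[MolecularSystem, float, np.ndarray]:
    """One velocity-Verlet step (half-kick, drift, half-kick).

    Returns the advanced system, the potential energy at the new positions,
    and the new gradient (reusable as the next step's ``gradient``).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    x = system.positions
    v = system.velocities
    inv_m = (EV_TO_KE / system.masses)[:, None]
    if gradient is None:
        _, gradient = pes.evaluate(x)
    v_half = v - 0.5 * dt * gradient * inv_m
    x_new = x + dt * v_half
    e_pot, g_new = pes.evaluate(x_new)
    v_new = v_half - 0.5 * dt * g_new * inv_m
    out = MolecularSystem(system.symbols, x_new, v_new, system.masses)
    return out, e_pot, g_new


def rescale_velocities(system: MolecularSystem, t_target: float) -> MolecularSystem:
    """Scale velocities uniformly so the kinetic temperature equals ``t_target``."""
    if t_target < 0:
        raise ValueError("target temperature must be non-negative")
    out = system.copy()
    if t_target == 0.0:
        out.velocities[:] = 0.0
        return out
    t_now = instantaneous_temperature(system)
    if t_now == 0.0:
        raise ValueError("cannot rescale zero kinetic energy to a finite T")
    out.velocities *= math.sqrt(t_target / t_now)
    return out


def _initial_thermal_velocities(system: MolecularSystem, t: float,
                                rng: np.random.Generator) -> np.ndarray:
    """Maxwell–Boltzmann draw with COM motion removed, rescaled to T exactly."""
    if t == 0.0:
        return np.zeros_like(system.positions)
    sigma = np.sqrt(K_BOLTZMANN_EV * t * EV_TO_KE / system.masses)
    v = rng.normal(size=(system.n_atoms, 3)) * sigma[:, None]
    v -= (system.masses @ v) / system.masses.sum()
    trial = MolecularSystem(system.symbols, system.positions, v, system.masses)
    return rescale_velocities(trial, t).velocities


def propagate_nvt(
    system: MolecularSystem,
    pes: PES,
    temperature: float,
    duration: float,
    dt: float = 0.5,
    rescale_stride: int = 10,
    sample_stride: int | None = None,
    seed: int = 0,
    equilibration: float = 0.0,
) -> list[MolecularSystem]:
    """Constant-temperature run with periodic velocity rescaling.

    Samples geometry+velocity snapshots every ``sample_stride`` steps of the
    production window (after ``equilibration`` fs).  If the initial state has
    zero kinetic energy, Maxwell–Boltzmann velocities at ``temperature`` are
    drawn from ``seed``.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    if sample_stride is None:
        sample_stride = max(int(round(100.0 / dt)), 1)  # every 100 fs
    rng = np.random.default_rng(seed)
    state = system.copy()
    if instantaneous_temperature(state) == 0.0 and temperature > 0:
        state.velocities = _initial_thermal_velocities(state, temperature, rng)
    n_steps = int(round(duration / dt))
    eq_steps = int(round(equilibration / dt))
    snapshots: list[MolecularSystem] = []
    gradient = None
    for step in range(1, n_steps + 1):
        state, _, gradient = velocity_verlet_step(state, pes, dt, gradient)
        if step % rescale_stride == 0 and temperature > 0:
            state = rescale_velocities(state, temperature)
        if step > eq_steps and step % sample_stride == 0:
            snapshots.append(state.copy())
    return snapshots


def propagate_nve(
    system: MolecularSystem,
    pes: PES,
    duration: float,
    dt: float = 0.5,
    sample_stride: int = 10,
    metadata: dict | None = None,
) -> Trajectory:
    """Constant-energy run; records (t, x, v, E_total) every ``sample_stride`` steps.

    If a non-finite energy is encountered the trajectory is truncated and
    flagged ``aborted`` — callers must treat this as distinct from a filter
    rejection.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    n_steps = int(round(duration / dt))
    state = system.copy()
    e_pot, gradient = pes.evaluate(state.positions)
    ke = _kinetic(state)
    times = [0.0]
    xs = [state.positions.copy()]
    vs = [state.velocities.copy()]
    es = [e_pot + ke]
    aborted = False
    for step in range(1, n_steps + 1):
        state, e_pot, gradient = velocity_verlet_step(state, pes, dt, gradient)
        if step % sample_stride == 0 or step == n_steps:
            e_tot = e_pot + _kinetic(state)
            if not np.isfinite(e_tot):
                aborted = True
                break
            times.append(step * dt)
            xs.append(state.positions.copy())
            vs.append(state.velocities.copy())
            es.append(e_tot)
    return Trajectory(
        np.array(times), np.array(xs), np.array(vs), np.array(es),
        list(system.symbols), system.masses.copy(),
        metadata=dict(metadata or {}), aborted=aborted,
    )


def _kinetic(system: MolecularSystem) -> float:
    v2 = np.einsum("ij,ij->i", system.velocities, system.velocities)
    return 0.5 * float(np.dot(system.masses, v2)) * KE_TO_EV


def energy_conservation_filter(trajectory: Trajectory, tol: float = 0.1) -> bool:
    """Accept a trajectory iff max_t |E(t) − E(0)| ≤ tol over stored frames.

    The bound is inclusive; the absolute deviation is used, so drifts of
    either sign count against the budget.  Aborted trajectories are never
    accepted.
    """
    if trajectory.aborted:
        return False
    e = trajectory.energies
    if len(e) == 0:
        raise ValueError("empty energy trace")
    return bool(np.max(np.abs(e - e[0])) <= tol)
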