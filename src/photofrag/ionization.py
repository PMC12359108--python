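"""The photoionization protocol.

Sudden vertical ionization out of a thermal ensemble: for each sampled
neutral geometry the vertical ionization potential IP = E_cation − E_neutral
is evaluated at fixed nuclei, the photon's excess energy E_hν − IP is
deposited entirely as nuclear kinetic energy through randomized velocities,
and the cation is propagated at constant energy.  The initial thermal
kinetic energy of the neutral, E_kin_ini = (3N − 6)/2 · kT (≈ 0.58 eV for a
12-atom molecule at 450 K), is *not* added to the deposit; instead photon
energies should be shifted down by that amount when compared with
experiment-style scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import K_BOLTZMANN_EV, KE_TO_EV, MolecularSystem
from .fragments import FragmentPartition, FragmentRecord, inventory_trajectory
from .md import Trajectory, energy_conservation_filter, propagate_nve, propagate_nvt
from .toy_pes import PES, ToyMoleculeSpec, ToyPES

__all__ = [
    "IonizationEvent",
    "EnsembleResult",
    "vertical_ip",
    "excess_energy",
    "thermal_kinetic_energy",
    "shifted_photon_energy",
    "sample_deposition_velocities",
    "run_ensemble",
]

_SEED_MASK = 0x7FFFFFFF


@dataclass(frozen=True)
class IonizationEvent:
    """Energy bookkeeping of one vertical ionization."""

    photon_energy: float  # eV
    vertical_ip: float  # eV
    deposited_kinetic: float  # E_hν − IP, eV (may be negative: no event)
    thermal_kinetic_ini: float  # diagnostic (3N−6)/2 kT term, eV
    seed: int

    @property
    def propagated(self) -> bool:
        return self.deposited_kinetic >= 0.0


@dataclass
class EnsembleResult:
    """Outcome of one photon energy's trajectory ensemble."""

    photon_energy: float
    events: list[IonizationEvent] = field(default_factory=list)
    trajectories: list[Trajectory] = field(default_factory=list)
    inventories: list[list[FragmentRecord]] = field(default_factory=list)
    final_partitions: list[FragmentPartition] = field(default_factory=list)
    n_requested: int = 0
    n_rejected: int = 0
    n_aborted: int = 0

    @property
    def n_accepted(self) -> int:
        return len(self.inventories)

    @property
    def fragmenting_fraction(self) -> float:
        if not self.final_partitions:
            return float("nan")
        frag = sum(1 for p in self.final_partitions if p.n_fragments > 1)
        return frag / len(self.final_partitions)


def vertical_ip(pes_neutral: PES, pes_cation: PES,
                positions: np.ndarray) -> float:
    """Cation-minus-neutral energy difference at fixed nuclear geometry (eV)."""
    e_n, _ = pes_neutral.evaluate(positions)
    e_c, _ = pes_cation.evaluate(positions)
    return e_c - e_n


def excess_energy(photon_energy: float, ip: float) -> float:
    """E_hν − IP in eV.  Negative means the photon cannot ionize."""
    return photon_energy - ip


def thermal_kinetic_energy(n_atoms: int, temperature: float) -> float:
    """Classical vibrational kinetic energy (3N − 6)/2 · kT in eV."""
    if n_atoms < 2 or temperature < 0:
        raise ValueError("need N ≥ 2 and T ≥ 0")
    dof = max(3 * n_atoms - 6, 0)
    return 0.5 * dof * K_BOLTZMANN_EV * temperature


def shifted_photon_energy(photon_energy: float, n_atoms: int,
                          temperature: float) -> float:
    """Photon energy minus the neglected thermal term, for comparison with
    experiment-style energy scales."""
    return photon_energy - thermal_kinetic_energy(n_atoms, temperature)


def sample_deposition_velocities(
    masses: np.ndarray, e_kin: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Random velocities carrying exactly ``e_kin`` eV with zero net momentum.

    Directions are drawn isotropically per atom (mass-independent Gaussian
    components), the center-of-mass momentum is projected out, and the
    result is rescaled uniformly so the total kinetic energy matches
    ``e_kin`` to machine precision.  Net angular momentum is *not* removed.
    """
    if e_kin < 0:
        raise ValueError("deposited kinetic energy must be non-negative")
    masses = np.asarray(masses, dtype=float)
    n = len(masses)
    if e_kin == 0.0:
        return np.zeros((n, 3))
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    v = rng.normal(size=(n, 3))
    v -= (masses @ v) / masses.sum()  # remove COM velocity
    ke = 0.5 * float(np.einsum("i,ij,ij->", masses, v, v)) * KE_TO_EV
    return v * np.sqrt(e_kin / ke)


def _trajectory_seed(base_seed: int, index: int) -> int:
    return (base_seed ^ index) & _SEED_MASK


def run_ensemble(
    spec: ToyMoleculeSpec,
    equilibrium: MolecularSystem,
    photon_grid: list[float],
    n_trajectories: int,
    temperature: float = 450.0,
    nvt_duration: float = 20_000.0,
    nve_duration: float = 10_000.0,
    dt: float = 0.5,
    sample_stride: int = 10,
    cutoff: float = 4.0,
    filter_tol: float = 0.1,
    base_seed: int = 1,
    nvt_sample_interval: float = 100.0,
    keep_trajectories: bool = True,
    snapshot_pool: list[MolecularSystem] | None = None,
) -> dict[float, EnsembleResult]:
    """Full protocol over a photon-energy grid.

    Thermal sampling on the neutral surface feeds one snapshot pool shared
    by all photon energies; trajectory i draws its snapshot and deposition
    velocities from seed ``base_seed XOR i``, so the ensemble is
    reproducible from (base_seed, trajectory index) and uses common random
    numbers across the grid.  Below-threshold events (E_hν < IP) are not
    propagated: the parent is counted intact.
    """
    pes_neutral = ToyPES(spec, "neutral")
    pes_cation = ToyPES(spec, "cation")
    if snapshot_pool is None:
        snapshot_pool = propagate_nvt(
            equilibrium, pes_neutral, temperature, nvt_duration, dt=dt,
            sample_stride=max(int(round(nvt_sample_interval / dt)), 1),
            seed=_trajectory_seed(base_seed, 0x5EED),
            equilibration=min(2000.0, 0.2 * nvt_duration),
        )
    if not snapshot_pool:
        raise ValueError("empty NVT snapshot pool")

    results: dict[float, EnsembleResult] = {}
    for photon_energy in photon_grid:
        res = EnsembleResult(photon_energy, n_requested=n_trajectories)
        for i in range(n_trajectories):
            seed = _trajectory_seed(base_seed, i)
            rng = np.random.default_rng(seed)
            snap = snapshot_pool[int(rng.integers(len(snapshot_pool)))]
            ip = vertical_ip(pes_neutral, pes_cation, snap.positions)
            e_dep = excess_energy(photon_energy, ip)
            event = IonizationEvent(
                photon_energy, ip, e_dep,
                thermal_kinetic_energy(snap.n_atoms, temperature), seed)
            res.events.append(event)
            if not event.propagated:
                # Parent survives untouched; single-frame "trajectory".
                start = MolecularSystem(snap.symbols, snap.positions.copy(),
                                        np.zeros_like(snap.positions),
                                        snap.masses.copy())
                e0, _ = pes_neutral.evaluate(start.positions)
                traj = Trajectory(
                    np.array([0.0]), start.positions[None], start.velocities[None],
                    np.array([e0]), list(start.symbols), start.masses.copy(),
                    metadata={"seed": seed, "E_hv_eV": photon_energy,
                              "surface": "neutral", "dt_fs": dt,
                              "propagated": 0})
            else:
                velocities = sample_deposition_velocities(
                    snap.masses, e_dep, rng)
                start = MolecularSystem(snap.symbols, snap.positions.copy(),
                                        velocities, snap.masses.copy())
                traj = propagate_nve(
                    start, pes_cation, nve_duration, dt=dt,
                    sample_stride=sample_stride,
                    metadata={"seed": seed, "E_hv_eV": photon_energy,
                              "IP_eV": ip, "E_dep_eV": e_dep,
                              "surface": "cation", "dt_fs": dt,
                              "propagated": 1})
                if traj.aborted:
                    res.n_aborted += 1
                    continue
                if not energy_conservation_filter(traj, filter_tol):
                    res.n_rejected += 1
                    continue
            records, final_part = inventory_trajectory(
                traj, cutoff=cutoff, ip_model=spec.ip_model)
            res.inventories.append(records)
            res.final_partitions.append(final_part)
            if keep_trajectories:
                res.trajectories.append(traj)
        results[photon_energy] = res
    return results
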