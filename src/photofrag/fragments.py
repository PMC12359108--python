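"""Fragment detection and bookkeeping on trajectory frames.

A frame fragments into the connected components of the graph whose edges
join every atom pair closer than the distance criterion (4 Å by default,
applied to *all* pairs, so transitive proximity keeps a chain together).
Exactly one component per frame carries the +1 charge, assigned by
Stevenson's rule: the fragment with the smallest vertical ionization
potential.  Fragment identity is the exact atom-index set, never the
formula — two isobaric species (e.g. the two kinds of 28 amu) stay
distinct records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .chem import ATOMIC_WEIGHTS, FragmentFormula, mass_bin, mass_label
from .md import Trajectory
from .toy_pes import FragmentIPModel

__all__ = [
    "detect_fragments",
    "assign_charge",
    "FragmentPartition",
    "FragmentRecord",
    "inventory_trajectory",
    "inventory_to_dataframe",
]


def detect_fragments(
    positions: np.ndarray, cutoff: float = 4.0
) -> list[tuple[int, ...]]:
    """Partition atoms into connected components of the ≤ cutoff graph.

    Returns sorted index tuples, ordered by their smallest member.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    x = np.asarray(positions, dtype=float)
    n = len(x)
    if n == 0:
        raise ValueError("no atoms")
    if n == 1:
        return [(0,)]
    adj = squareform(pdist(x) <= cutoff)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups: dict[int, list[int]] = {}
    for atom, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(atom)
    return sorted((tuple(g) for g in groups.values()), key=lambda g: g[0])


def _set_mass(symbols: Sequence[str], atom_set: Iterable[int]) -> float:
    return sum(ATOMIC_WEIGHTS[symbols[i]] for i in atom_set)


def assign_charge(
    partition: Sequence[tuple[int, ...]],
    ip_model: FragmentIPModel,
) -> int:
    """Index (into ``partition``) of the set that carries the +1 charge.

    Stevenson's rule: smallest vertical IP wins; exact ties go to the
    heavier fragment, then to the set with the smaller lowest atom index.
    """
    if not partition:
        raise ValueError("empty partition")
    best = None
    for idx, atom_set in enumerate(partition):
        key = (ip_model.ip(atom_set),
               -_set_mass(ip_model.symbols, atom_set),
               atom_set[0])
        if best is None or key < best[0]:
            best = (key, idx)
    return best[1]


@dataclass
class FragmentPartition:
    """One frame's disjoint fragments with formulas, masses and the cation flag."""

    time_fs: float
    sets: list[tuple[int, ...]]
    formulas: list[FragmentFormula]
    cation_index: int

    @property
    def n_fragments(self) -> int:
        return len(self.sets)

    @property
    def cation_set(self) -> tuple[int, ...]:
        return self.sets[self.cation_index]

    @property
    def cation_formula(self) -> FragmentFormula:
        return self.formulas[self.cation_index]


@dataclass
class FragmentRecord:
    """Lifetime bookkeeping of one exact atom set across a trajectory."""

    atom_set: tuple[int, ...]
    formula: str
    mass: float  # two-decimal label, amu
    mz: int  # nearest-integer bin
    first_time_fs: float
    survived: bool = False
    cation_final: bool = False
    ever_cation: bool = False  # flagged cation in any frame (incl. transients)
    parent_set: tuple[int, ...] | None = None
    parent_formula: str | None = None


def _partition_frame(symbols, positions, time_fs, cutoff, ip_model):
    sets = detect_fragments(positions, cutoff)
    formulas = [FragmentFormula.from_symbols(symbols[i] for i in s)
                for s in sets]
    cation = assign_charge(sets, ip_model) if ip_model is not None else 0
    return FragmentPartition(time_fs, sets, formulas, cation)


def inventory_trajectory(
    trajectory: Trajectory,
    cutoff: float = 4.0,
    ip_model: FragmentIPModel | None = None,
) -> tuple[list[FragmentRecord], FragmentPartition]:
    """Per-frame partitions condensed into fragment records.

    A record is created the first time its exact atom set appears; its
    parent is the previous frame's set that contained it.  ``survived``
    means the set is present in the final frame; the final frame's charge
    assignment is the one spectra consume, while ``ever_cation`` also marks
    transient cations.
    """
    if trajectory.n_frames == 0:
        raise ValueError("empty trajectory")
    symbols = trajectory.symbols
    records: dict[tuple[int, ...], FragmentRecord] = {}
    prev_sets: list[tuple[int, ...]] = []
    final_partition = None
    for k in range(trajectory.n_frames):
        part = _partition_frame(symbols, trajectory.positions[k],
                                float(trajectory.times[k]), cutoff, ip_model)
        for idx, atom_set in enumerate(part.sets):
            if atom_set not in records:
                parent = next((p for p in prev_sets
                               if set(atom_set) < set(p)), None)
                formula = part.formulas[idx]
                records[atom_set] = FragmentRecord(
                    atom_set, formula.hill,
                    mass_label(formula), mass_bin(formula),
                    part.time_fs,
                    parent_set=parent,
                    parent_formula=(
                        FragmentFormula.from_symbols(
                            symbols[i] for i in parent).hill
                        if parent else None),
                )
            if ip_model is not None and idx == part.cation_index:
                records[atom_set].ever_cation = True
        prev_sets = part.sets
        final_partition = part
    for idx, atom_set in enumerate(final_partition.sets):
        rec = records[atom_set]
        rec.survived = True
        rec.cation_final = (ip_model is not None
                            and idx == final_partition.cation_index)
    return list(records.values()), final_partition


def inventory_to_dataframe(
    records_per_trajectory: dict[int, list[FragmentRecord]]
) -> pd.DataFrame:
    """Flatten inventories into one row per fragment record."""
    rows = []
    for traj_id, records in records_per_trajectory.items():
        for r in records:
            rows.append({
                "trajectory": traj_id,
                "formula": r.formula,
                "mass": r.mass,
                "mz": r.mz,
                "first_time_fs": r.first_time_fs,
                "survived": r.survived,
                "cation": r.cation_final,
                "ever_cation": r.ever_cation,
                "parent_formula": r.parent_formula,
                "atom_set": ",".join(map(str, r.atom_set)),
            })
    return pd.DataFrame(rows)
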