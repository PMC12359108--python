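"""Atomic data, molecular state container, formula arithmetic and XYZ I/O.

Unit system used throughout the package: length in Å, time in fs, mass in
amu, energy in eV.  A single conversion constant relates the mechanical
energy unit amu·Å²/fs² to eV (see :data:`KE_TO_EV`); forces in eV/Å are
converted to accelerations in Å/fs² with its inverse.

Fragment masses use *average* atomic weights, not monoisotopic masses, so
that isobaric species such as CO (28.01 amu) and HCNH (28.03 amu) carry
distinct two-decimal labels while binning to the same integer m/z.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ATOMIC_WEIGHTS",
    "KE_TO_EV",
    "EV_TO_KE",
    "K_BOLTZMANN_EV",
    "MolecularSystem",
    "FragmentFormula",
    "molecular_formula",
    "parse_formula",
    "fragment_mass",
    "mass_label",
    "mass_bin",
    "kinetic_energy",
    "center_of_mass_momentum",
    "read_xyz",
    "write_xyz",
]

#: Average atomic weights in amu (IUPAC conventional values).
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "F": 18.998,
    "Cl": 35.45,
}

#: 1 amu·(Å/fs)² expressed in eV.  Derived from CODATA values of the
#: atomic mass constant and the elementary charge; this is the only
#: mechanical unit conversion in the package.
KE_TO_EV: float = 1.66053906660e-27 * 1.0e10 / 1.602176634e-19  # ≈ 103.6427

#: Inverse conversion: acceleration (Å/fs²) = force (eV/Å) / mass (amu) * EV_TO_KE.
EV_TO_KE: float = 1.0 / KE_TO_EV

#: Boltzmann constant in eV/K.
K_BOLTZMANN_EV: float = 8.617333262e-5


@dataclass
class MolecularSystem:
    """Cartesian state of one molecule: symbols, positions, velocities.

    Positions in Å, velocities in Å/fs.  Masses (amu) are derived from the
    symbols via :data:`ATOMIC_WEIGHTS` unless given explicitly.
    """

    symbols: list[str]
    positions: np.ndarray
    velocities: np.ndarray | None = None
    masses: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.symbols = list(self.symbols)
        n = len(self.symbols)
        if n < 1:
            raise ValueError("a molecular system needs at least one atom")
        self.positions = np.asarray(self.positions, dtype=float).reshape(n, 3)
        if self.velocities is None:
            self.velocities = np.zeros((n, 3))
        self.velocities = np.asarray(self.velocities, dtype=float).reshape(n, 3)
        if self.masses is None:
            try:
                self.masses = np.array([ATOMIC_WEIGHTS[s] for s in self.symbols])
            except KeyError as exc:  # pragma: no cover - defensive
                raise KeyError(f"unknown element symbol {exc}") from None
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.shape != (n,):
            raise ValueError("masses must have one entry per atom")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def copy(self) -> "MolecularSystem":
        return MolecularSystem(
            list(self.symbols),
            self.positions.copy(),
            self.velocities.copy(),
            self.masses.copy(),
        )


# Hill order: carbon first, hydrogen second, remaining elements alphabetical;
# without carbon, everything alphabetical.
def _hill_sort_key(formula_has_carbon: bool):
    def key(element: str):
        if formula_has_carbon:
            if element == "C":
                return (0, "")
            if element == "H":
                return (1, "")
            return (2, element)
        return (0, element)

    return key


@dataclass(frozen=True)
class FragmentFormula:
    """Element-count multiset with a canonical Hill-order string."""

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("formula must contain at least one element")
        for elem, cnt in self.counts:
            if cnt <= 0:
                raise ValueError(f"non-positive count for {elem}")
            if elem not in ATOMIC_WEIGHTS:
                raise KeyError(f"unknown element symbol {elem!r}")

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "FragmentFormula":
        items = {e: int(c) for e, c in counts.items() if c}
        has_c = "C" in items
        ordered = tuple(
            (e, items[e]) for e in sorted(items, key=_hill_sort_key(has_c))
        )
        return cls(ordered)

    @classmethod
    def from_symbols(cls, symbols: Iterable[str]) -> "FragmentFormula":
        return cls.from_counts(Counter(symbols))

    @property
    def hill(self) -> str:
        return "".join(
            f"{e}{c}" if c > 1 else e for e, c in self.counts
        )

    @property
    def mass(self) -> float:
        """Average-weight mass in amu."""
        return sum(ATOMIC_WEIGHTS[e] * c for e, c in self.counts)

    @property
    def n_atoms(self) -> int:
        return sum(c for _, c in self.counts)

    def __str__(self) -> str:
        return self.hill


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> FragmentFormula:
    """Parse a plain formula string like ``"C2H3N"`` into a :class:`FragmentFormula`."""
    counts: Counter[str] = Counter()
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"malformed formula {formula!r}")
        pos = match.end()
        elem, num = match.groups()
        counts[elem] += int(num) if num else 1
    if pos != len(formula) or not counts:
        raise ValueError(f"malformed formula {formula!r}")
    return FragmentFormula.from_counts(counts)


def molecular_formula(
    system: MolecularSystem, atom_indices: Iterable[int]
) -> FragmentFormula:
    """Formula of the sub-molecule formed by ``atom_indices`` of ``system``."""
    indices = list(atom_indices)
    if not indices:
        raise ValueError("empty atom index set")
    return FragmentFormula.from_symbols(system.symbols[i] for i in indices)


def fragment_mass(formula: FragmentFormula | str) -> float:
    """Average-weight mass of a formula in amu."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return formula.mass


def mass_label(formula: FragmentFormula | str) -> float:
    """Two-decimal mass label, e.g. 28.03 for HCNH vs 28.01 for CO."""
    return round(fragment_mass(formula), 2)


def mass_bin(formula: FragmentFormula | str) -> int:
    """Nearest-integer m/z bin (z = 1 everywhere in this package)."""
    return int(round(fragment_mass(formula)))


def kinetic_energy(system: MolecularSystem) -> float:
    """Total nuclear kinetic energy Σ ½ m v² in eV."""
    v2 = np.einsum("ij,ij->i", system.velocities, system.velocities)
    return 0.5 * float(np.dot(system.masses, v2)) * KE_TO_EV


def center_of_mass_momentum(system: MolecularSystem) -> np.ndarray:
    """Total linear momentum Σ m v in amu·Å/fs."""
    return system.masses @ system.velocities


# ---------------------------------------------------------------------------
# Extended-XYZ I/O.  The comment line carries whitespace-separated key=value
# pairs (e.g. "time_fs=5.0 E_tot_eV=-1.234 charge=1").  When velocities are
# present they are written as three extra columns after the coordinates.
# ---------------------------------------------------------------------------

_FLOAT_FMT = "{:20.12f}"


def _parse_comment(comment: str) -> dict[str, float | int | str]:
    meta: dict[str, float | int | str] = {}
    for token in comment.split():
        if "=" not in token:
            continue
        key, _, raw = token.partition("=")
        try:
            val: float | int | str = int(raw)
        except ValueError:
            try:
                val = float(raw)
            except ValueError:
                val = raw
        meta[key] = val
    return meta


def read_xyz(path: str | Path) -> list[tuple[MolecularSystem, dict]]:
    """Read a (multi-frame) XYZ file.

    Returns a list of ``(system, metadata)`` pairs, one per frame, where
    ``metadata`` holds the parsed key=value pairs of the comment line.
    """
    frames: list[tuple[MolecularSystem, dict]] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError:
            raise ValueError(f"malformed XYZ header at line {i + 1}") from None
        if i + 2 + n > len(lines):
            raise ValueError("atom-count mismatch: truncated frame")
        meta = _parse_comment(lines[i + 1])
        symbols, pos, vel = [], [], []
        has_vel = None
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) not in (4, 7):
                raise ValueError(f"malformed atom line {i + 3 + j}")
            if has_vel is None:
                has_vel = len(parts) == 7
            symbols.append(parts[0])
            pos.append([float(x) for x in parts[1:4]])
            if has_vel:
                vel.append([float(x) for x in parts[4:7]])
        system = MolecularSystem(
            symbols, np.array(pos), np.array(vel) if vel else None
        )
        frames.append((system, meta))
        i += 2 + n
    return frames


def write_xyz(
    frames: Sequence[MolecularSystem | tuple[MolecularSystem, Mapping]],
    path: str | Path,
    write_velocities: bool = False,
) -> None:
    """Write one or many frames as (extended) XYZ with key=value comments."""
    out: list[str] = []
    for frame in frames:
        system, meta = frame if isinstance(frame, tuple) else (frame, {})
        out.append(str(system.n_atoms))
        out.append(" ".join(f"{k}={v}" for k, v in meta.items()))
        for k, sym in enumerate(system.symbols):
            cols = [f"{sym:<3s}"] + [
                _FLOAT_FMT.format(x) for x in system.positions[k]
            ]
            if write_velocities:
                cols += [_FLOAT_FMT.format(x) for x in system.velocities[k]]
            out.append(" ".join(cols))
    Path(path).write_text("\n".join(out) + "\n")
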