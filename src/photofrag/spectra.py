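"""Ensemble summaries: relative abundances, energy-resolved mass spectra,
breakdown diagrams and first-occurrence trees.

The relative abundance of fragment i is F_i = N_i / Σ_j N_j.  In
all-fragments mode the counts run over every surviving final-frame fragment
(neutrals and the cation, the intact parent included); in cations-only mode
only each accepted trajectory's final cation is counted, so the denominator
equals the number of accepted trajectories and the table reads as a mass
spectrum (z = 1 throughout).  Labels are (integer m/z, formula) pairs so
isobars — the two kinds of 28 amu, say — never merge silently.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ionization import EnsembleResult

__all__ = [
    "SpectrumLabel",
    "AbundanceTable",
    "relative_abundance",
    "all_fragment_counts",
    "cation_counts",
    "mass_spectrum",
    "all_fragment_abundances",
    "BreakdownDiagram",
    "breakdown_diagram",
    "crossing_energy",
    "first_occurrence_tree",
]

#: (integer m/z, Hill formula)
SpectrumLabel = tuple[int, str]


@dataclass
class AbundanceTable:
    """Normalized fragment abundances at one photon energy."""

    photon_energy: float
    mode: str  # "all-fragments" | "cations-only"
    abundances: dict[SpectrumLabel, float]
    denominator: int

    def __post_init__(self) -> None:
        if self.mode not in ("all-fragments", "cations-only"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def get(self, label: SpectrumLabel) -> float:
        return self.abundances.get(label, 0.0)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"mz": mz, "formula": f, "abundance": v}
                for (mz, f), v in sorted(self.abundances.items())]
        return pd.DataFrame(rows)

    def binned(self) -> dict[int, float]:
        """Pure-integer m/z export: isobars summed into one bin."""
        out: dict[int, float] = {}
        for (mz, _), v in self.abundances.items():
            out[mz] = out.get(mz, 0.0) + v
        return out


def relative_abundance(
    counts: Mapping[SpectrumLabel, int],
    photon_energy: float = float("nan"),
    mode: str = "all-fragments",
) -> AbundanceTable:
    """Normalize raw fragment counts: F_i = N_i / Σ_j N_j."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("all-zero counts")
    if any(c < 0 for c in counts.values()):
        raise ValueError("negative count")
    ab = {label: c / total for label, c in counts.items() if c > 0}
    return AbundanceTable(photon_energy, mode, ab, total)


def all_fragment_counts(result: EnsembleResult) -> Counter:
    """Counts of every surviving final-frame fragment (neutral or cationic)."""
    counts: Counter = Counter()
    for part in result.final_partitions:
        for formula in part.formulas:
            counts[(int(round(formula.mass)), formula.hill)] += 1
    return counts


def cation_counts(result: EnsembleResult) -> Counter:
    """Counts of each accepted trajectory's final-frame cation."""
    counts: Counter = Counter()
    for part in result.final_partitions:
        formula = part.cation_formula
        counts[(int(round(formula.mass)), formula.hill)] += 1
    return counts


def mass_spectrum(result: EnsembleResult) -> AbundanceTable:
    """Cations-only abundance table; denominator = accepted trajectories."""
    table = relative_abundance(cation_counts(result), result.photon_energy,
                               mode="cations-only")
    assert table.denominator == result.n_accepted
    return table


def all_fragment_abundances(result: EnsembleResult) -> AbundanceTable:
    """All-fragments abundance table (neutrals and cations together)."""
    return relative_abundance(all_fragment_counts(result),
                              result.photon_energy, mode="all-fragments")


@dataclass
class BreakdownDiagram:
    """Per-label abundance curves versus photon energy."""

    energies: list[float]
    curves: dict[SpectrumLabel, np.ndarray]
    mode: str

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {f"{mz}:{formula}": curve
             for (mz, formula), curve in sorted(self.curves.items())},
            index=pd.Index(self.energies, name="photon_energy_eV"),
        )
        return df


def breakdown_diagram(tables: Sequence[AbundanceTable]) -> BreakdownDiagram:
    """Align abundance tables over the photon grid; absent labels become 0."""
    if len(tables) < 2:
        raise ValueError("need at least two photon energies")
    modes = {t.mode for t in tables}
    if len(modes) != 1:
        raise ValueError("inconsistent table modes")
    tables = sorted(tables, key=lambda t: t.photon_energy)
    energies = [t.photon_energy for t in tables]
    labels = sorted({lab for t in tables for lab in t.abundances})
    curves = {lab: np.array([t.get(lab) for t in tables]) for lab in labels}
    return BreakdownDiagram(energies, curves, modes.pop())


def crossing_energy(
    diagram: BreakdownDiagram,
    label_a: SpectrumLabel,
    label_b: SpectrumLabel,
) -> float | None:
    """Photon energy where curve a first crosses below curve b (linear
    interpolation between grid points); None if they never cross."""
    a = diagram.curves[label_a]
    b = diagram.curves[label_b]
    d = a - b
    for k in range(1, len(d)):
        if d[k - 1] > 0 >= d[k]:
            e0, e1 = diagram.energies[k - 1], diagram.energies[k]
            frac = d[k - 1] / (d[k - 1] - d[k]) if d[k - 1] != d[k] else 0.0
            return e0 + frac * (e1 - e0)
    return None


def first_occurrence_tree(
    results: Mapping[float, EnsembleResult]
) -> pd.DataFrame:
    """Lowest photon energy at which each distinct formula appears, with its
    most common parent fragment.

    Transient fragments count here (they appeared), even though they are
    excluded from the abundance tables.
    """
    first_energy: dict[SpectrumLabel, float] = {}
    parents: dict[SpectrumLabel, Counter] = {}
    ever_cation: dict[SpectrumLabel, bool] = {}
    for energy in sorted(results):
        for records in results[energy].inventories:
            for rec in records:
                label = (rec.mz, rec.formula)
                if label not in first_energy or energy < first_energy[label]:
                    first_energy[label] = energy
                parents.setdefault(label, Counter())
                if rec.parent_formula is not None:
                    parents[label][rec.parent_formula] += 1
                ever_cation[label] = ever_cation.get(label, False) or rec.ever_cation
    rows = []
    for label in sorted(first_energy, key=lambda l: (-l[0], l[1])):
        mz, formula = label
        common = parents[label].most_common(1)
        rows.append({
            "mz": mz,
            "formula": formula,
            "first_photon_energy_eV": first_energy[label],
            "parent_formula": common[0][0] if common else None,
            "ever_cation": ever_cation[label],
        })
    return pd.DataFrame(rows)
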