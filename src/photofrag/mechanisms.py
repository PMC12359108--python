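"""Reaction-mechanism reconstruction from trajectories.

Bond-break and bond-formation events are detected with hysteresis: a bonded
pair must stay beyond ``break_factor × r0`` for a dwell window before a
break is recorded (and symmetrically for formation), which suppresses
vibrational flicker across the threshold.  Hydrogen transfer is detected by
a change of a hydrogen's nearest heavy neighbor that persists for the dwell
window.  Dissociation times use the same distance-graph criterion as the
fragment inventory, so a trajectory's dissociation time is never earlier
than its first break event is late — breaks (threshold crossing at ~2 r0)
always precede the 4 Å separation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fragments import detect_fragments
from .md import Trajectory
from .toy_pes import BondTerm

__all__ = [
    "BondEvent",
    "MechanismSignature",
    "bond_event_timeline",
    "detect_h_transfer",
    "dissociation_time",
    "mean_dissociation_time",
    "mechanism_signature",
    "tally_signatures",
    "events_to_dataframe",
]

#: Generic equilibrium lengths (Å) used to watch *new* heavy-atom contacts
#: that are not part of the reference topology.
_GENERIC_R0 = {
    frozenset(("C", "C")): 1.40, frozenset(("C", "N")): 1.38,
    frozenset(("C", "O")): 1.25, frozenset(("C", "S")): 1.70,
    frozenset(("N", "N")): 1.35, frozenset(("N", "O")): 1.25,
    frozenset(("N", "S")): 1.65, frozenset(("O", "S")): 1.60,
    frozenset(("O", "O")): 1.30, frozenset(("S", "S")): 2.00,
}


@dataclass(frozen=True)
class BondEvent:
    kind: str  # "break" | "form" | "H-transfer"
    atoms: tuple[int, ...]
    time_fs: float
    label: str = ""
    donor: int | None = None  # H-transfer only: heavy atoms
    acceptor: int | None = None


def _atom_label(symbols: Sequence[str], i: int) -> str:
    return f"{symbols[i]}{i}"


def _pair_label(symbols: Sequence[str], i: int, j: int) -> str:
    return f"{_atom_label(symbols, i)}-{_atom_label(symbols, j)}"


def _pair_distances(trajectory: Trajectory,
                    pairs: Sequence[tuple[int, int]]) -> np.ndarray:
    idx_i = np.array([p[0] for p in pairs])
    idx_j = np.array([p[1] for p in pairs])
    d = trajectory.positions[:, idx_i] - trajectory.positions[:, idx_j]
    return np.linalg.norm(d, axis=2)  # (n_frames, n_pairs)


def _dwell_frames(trajectory: Trajectory, dwell_fs: float) -> int:
    if trajectory.n_frames < 2:
        return 1
    frame_dt = float(trajectory.times[1] - trajectory.times[0])
    return max(int(np.ceil(dwell_fs / frame_dt)), 1)


def bond_event_timeline(
    trajectory: Trajectory,
    reference_bonds: Sequence[BondTerm | tuple[int, int, float]],
    break_factor: float = 1.8,
    form_factor: float = 1.3,
    dwell_fs: float = 50.0,
    watch_new_contacts: bool = True,
) -> list[BondEvent]:
    """Time-ordered break/form events with hysteresis and a dwell window.

    ``reference_bonds`` supplies the initially bonded pairs and their r0
    (BondTerm objects or ``(i, j, r0)`` tuples).  With
    ``watch_new_contacts`` every heavy-atom pair outside the topology is
    also monitored for formation, using generic element-pair lengths.
    Events are time-stamped at the start of their dwell window.
    """
    symbols = trajectory.symbols
    pairs: list[tuple[int, int]] = []
    r0s: list[float] = []
    bonded0: list[bool] = []
    for b in reference_bonds:
        i, j, r0 = (b.i, b.j, b.r0) if isinstance(b, BondTerm) else b
        pairs.append((i, j))
        r0s.append(r0)
        bonded0.append(True)
    if watch_new_contacts:
        known = {frozenset(p) for p in pairs}
        heavy = [i for i, s in enumerate(symbols) if s != "H"]
        for a in range(len(heavy)):
            for b2 in range(a + 1, len(heavy)):
                i, j = heavy[a], heavy[b2]
                if frozenset((i, j)) in known:
                    continue
                key = frozenset((symbols[i], symbols[j]))
                pairs.append((i, j))
                r0s.append(_GENERIC_R0.get(key, 1.6))
                bonded0.append(False)

    dist = _pair_distances(trajectory, pairs)
    dwell = _dwell_frames(trajectory, dwell_fs)
    n_frames = trajectory.n_frames
    events: list[BondEvent] = []
    for p, (i, j) in enumerate(pairs):
        bonded = bonded0[p]
        hi = break_factor * r0s[p]
        lo = form_factor * r0s[p]
        run_start = None  # frame index where the current excursion began
        for k in range(n_frames):
            d = dist[k, p]
            crossing = (d > hi) if bonded else (d < lo)
            if crossing:
                if run_start is None:
                    run_start = k
                if k - run_start + 1 >= dwell:
                    kind = "break" if bonded else "form"
                    events.append(BondEvent(
                        kind, (i, j), float(trajectory.times[run_start]),
                        _pair_label(symbols, i, j)))
                    bonded = not bonded
                    run_start = None
            else:
                run_start = None
    events.sort(key=lambda e: (e.time_fs, e.atoms))
    return events


def detect_h_transfer(
    trajectory: Trajectory, dwell_fs: float = 50.0
) -> list[BondEvent]:
    """H-transfer events: a hydrogen's nearest heavy neighbor changes and
    the new assignment persists for the dwell window."""
    symbols = trajectory.symbols
    hydrogens = [i for i, s in enumerate(symbols) if s == "H"]
    heavies = np.array([i for i, s in enumerate(symbols) if s != "H"])
    if not hydrogens or not len(heavies):
        return []
    dwell = _dwell_frames(trajectory, dwell_fs)
    events: list[BondEvent] = []
    for h in hydrogens:
        d = np.linalg.norm(
            trajectory.positions[:, h, None, :]
            - trajectory.positions[:, heavies, :], axis=2)
        nearest = heavies[np.argmin(d, axis=1)]
        owner = int(nearest[0])
        cand = None
        run_start = None
        for k in range(1, trajectory.n_frames):
            cur = int(nearest[k])
            if cur == owner:
                cand, run_start = None, None
                continue
            if cur != cand:
                cand, run_start = cur, k
            if k - run_start + 1 >= dwell:
                events.append(BondEvent(
                    "H-transfer", (h,), float(trajectory.times[run_start]),
                    f"{_atom_label(symbols, h)}:"
                    f"{_atom_label(symbols, owner)}→{_atom_label(symbols, cur)}",
                    donor=owner, acceptor=cur))
                owner = cur
                cand, run_start = None, None
    events.sort(key=lambda e: (e.time_fs, e.atoms))
    return events


def dissociation_time(trajectory: Trajectory,
                      cutoff: float = 4.0) -> float | None:
    """First stored-frame time after which the molecule stays fragmented.

    None if the final frame is a single connected piece (including the case
    of transient separations that recombined).
    """
    n_frag = np.array([
        len(detect_fragments(trajectory.positions[k], cutoff))
        for k in range(trajectory.n_frames)
    ])
    if n_frag[-1] == 1:
        return None
    whole = np.nonzero(n_frag == 1)[0]
    k = whole[-1] + 1 if len(whole) else 0
    return float(trajectory.times[k])


def mean_dissociation_time(
    trajectories: Iterable[Trajectory], cutoff: float = 4.0
) -> float:
    """Mean dissociation time (fs) over fragmenting trajectories only;
    NaN if none fragmented."""
    times = [t for t in (dissociation_time(tr, cutoff) for tr in trajectories)
             if t is not None]
    return float(np.mean(times)) if times else float("nan")


@dataclass
class MechanismSignature:
    """Ordered event string up to first stable fragmentation, plus the
    final fragment formulas."""

    events: list[BondEvent]
    final_formulas: tuple[str, ...]

    @property
    def key(self) -> str:
        steps = "; ".join(f"{e.kind}({e.label})" for e in self.events)
        return f"[{steps}] -> {'+'.join(self.final_formulas)}"


def mechanism_signature(
    trajectory: Trajectory,
    reference_bonds: Sequence[BondTerm | tuple[int, int, float]],
    cutoff: float = 4.0,
    include_h_transfer: bool = True,
    **timeline_kwargs,
) -> MechanismSignature:
    """Canonical mechanism of one trajectory.

    Events later than the stable-fragmentation time are dropped (they
    describe post-dissociation rearrangement, not the mechanism).
    """
    from .chem import FragmentFormula

    events = bond_event_timeline(trajectory, reference_bonds,
                                 **timeline_kwargs)
    if include_h_transfer:
        events = sorted(events + detect_h_transfer(trajectory),
                        key=lambda e: (e.time_fs, e.atoms))
    t_diss = dissociation_time(trajectory, cutoff)
    if t_diss is not None:
        events = [e for e in events if e.time_fs <= t_diss]
    final_sets = detect_fragments(trajectory.positions[-1], cutoff)
    formulas = tuple(sorted(
        FragmentFormula.from_symbols(
            trajectory.symbols[i] for i in s).hill
        for s in final_sets))
    return MechanismSignature(events, formulas)


def tally_signatures(
    trajectories: Iterable[Trajectory],
    reference_bonds: Sequence[BondTerm | tuple[int, int, float]],
    **kwargs,
) -> Counter:
    """Frequency tally of mechanism signatures over an ensemble."""
    tally: Counter = Counter()
    for tr in trajectories:
        tally[mechanism_signature(tr, reference_bonds, **kwargs).key] += 1
    return tally


def events_to_dataframe(
    events_per_trajectory: Mapping[int, Sequence[BondEvent]]
) -> pd.DataFrame:
    rows = []
    for traj_id, events in events_per_trajectory.items():
        for e in events:
            rows.append({"trajectory": traj_id, "time_fs": e.time_fs,
                         "kind": e.kind, "label": e.label,
                         "atoms": ",".join(map(str, e.atoms))})
    return pd.DataFrame(rows)
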