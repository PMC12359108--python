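"""Synthetic reactive potential for a 12-atom thiouracil-like ring.

The package's dynamics and analysis stages are written against a generic
potential contract (:class:`PES`): anything that maps Cartesian positions to
an energy and gradient, tagged with a charge state, can drive them.  This
module provides the bundled implementation — a bonded Morse + switched-angle
potential on a six-membered (4 C + 2 N) ring carrying exocyclic O, S and four
H atoms.  Morse bonds dissociate cleanly, angle terms switch off smoothly as
either flanking bond stretches, so the surface supports both bound vibration
and fragmentation.

Two surfaces are defined per fixture:

* the neutral ground-state surface, whose heavy-atom well depths follow the
  literature ordering for uracil-like rings (ring C–N single bonds weakest,
  ~3.42 eV ≈ 330 kJ/mol, vs ~3.81 eV ≈ 368 kJ/mol for C–C);
* the cation surface, the same bonded topology with strongly softened wells
  (ionization removes bonding electron density) plus a constant shift
  calibrated so the vertical ionization potential at the equilibrium
  geometry matches the target (8.73 eV for the 2-thiouracil-like variant,
  8.54 eV for the 4-thiouracil-like one).  Equilibrium-bond-length shifts on
  the two weakest C–N bonds make the vertical IP geometry dependent, with a
  spread of roughly 0.1 eV over a 450 K thermal ensemble.

A deterministic fragment ionization-potential model (:class:`FragmentIPModel`)
assigns a vertical IP to every atom subset of the fixture, which is what the
Stevenson-rule charge assignment consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Protocol, Sequence

import numpy as np
from scipy.special import expit

from .chem import MolecularSystem

__all__ = [
    "PES",
    "BondTerm",
    "AngleTerm",
    "ToyMoleculeSpec",
    "ToyPES",
    "FragmentIPModel",
    "fragment_ip",
    "toy_fixture",
    "KJMOL_TO_EV",
]

#: kJ/mol per eV (molar Faraday-type conversion).
KJMOL_TO_EV = 1.0 / 96.485


class PES(Protocol):
    """Potential contract: energy/gradient provider for one charge state."""

    charge_state: str  # "neutral" | "cation"

    def evaluate(self, positions: np.ndarray) -> tuple[float, np.ndarray]:
        """Return (energy in eV, gradient dE/dx in eV/Å, shape (N, 3))."""
        ...


@dataclass(frozen=True)
class BondTerm:
    i: int
    j: int
    d_e: float  # well depth, eV
    r0: float  # equilibrium length, Å
    a: float  # Morse width, 1/Å
    label: str = ""


@dataclass(frozen=True)
class AngleTerm:
    """Harmonic-in-cosine angle i–j–k (j is the apex).

    The term is multiplied by a sigmoid switching function of each flanking
    bond length so it vanishes smoothly when either bond dissociates.
    """

    i: int
    j: int
    k: int
    k_theta: float  # eV
    cos0: float
    r_sw_ij: float  # switch midpoint for bond j–i, Å
    r_sw_jk: float
    w_sw: float = 0.08  # switch width, Å


@dataclass
class ToyMoleculeSpec:
    """Topology + force-field parameters of the 12-atom fixture."""

    variant: str
    symbols: list[str]
    bonds: list[BondTerm]
    angles: list[AngleTerm]
    cation_bonds: list[BondTerm]
    cation_offset: float  # constant shift of the cation surface, eV
    ip_model: "FragmentIPModel"

    def to_dict(self) -> dict:
        """Serializable description (element list, bond tables, IP parameters)."""
        return {
            "variant": self.variant,
            "symbols": list(self.symbols),
            "bonds": [
                {"i": b.i, "j": b.j, "D_e_eV": b.d_e, "r0_A": b.r0,
                 "a_invA": b.a, "label": b.label}
                for b in self.bonds
            ],
            "cation_bonds": [
                {"i": b.i, "j": b.j, "D_e_eV": b.d_e, "r0_A": b.r0,
                 "a_invA": b.a, "label": b.label}
                for b in self.cation_bonds
            ],
            "cation_offset_eV": self.cation_offset,
            "ip_model": self.ip_model.to_dict(),
        }


class ToyPES:
    """Morse + switched-angle surface for one charge state of a fixture."""

    def __init__(self, spec: ToyMoleculeSpec,
                 charge_state: Literal["neutral", "cation"] = "neutral"):
        self.spec = spec
        self.charge_state = charge_state
        bonds = spec.bonds if charge_state == "neutral" else spec.cation_bonds
        self.offset = 0.0 if charge_state == "neutral" else spec.cation_offset
        self._bi = np.array([b.i for b in bonds])
        self._bj = np.array([b.j for b in bonds])
        self._de = np.array([b.d_e for b in bonds])
        self._r0 = np.array([b.r0 for b in bonds])
        self._a = np.array([b.a for b in bonds])
        ang = spec.angles
        self._ai = np.array([t.i for t in ang])
        self._aj = np.array([t.j for t in ang])
        self._ak = np.array([t.k for t in ang])
        self._kt = np.array([t.k_theta for t in ang])
        self._c0 = np.array([t.cos0 for t in ang])
        self._rs_ij = np.array([t.r_sw_ij for t in ang])
        self._rs_jk = np.array([t.r_sw_jk for t in ang])
        self._wsw = np.array([t.w_sw for t in ang])
        self.n_atoms = len(spec.symbols)

    def evaluate(self, positions: np.ndarray) -> tuple[float, np.ndarray]:
        x = np.asarray(positions, dtype=float).reshape(self.n_atoms, 3)
        grad = np.zeros_like(x)

        # Morse bonds: V = De (1 - exp(-a (r - r0)))^2
        dvec = x[self._bj] - x[self._bi]
        r = np.linalg.norm(dvec, axis=1)
        ex = np.exp(-self._a * (r - self._r0))
        one = 1.0 - ex
        energy = float(np.sum(self._de * one * one))
        dv_dr = 2.0 * self._de * self._a * one * ex  # dV/dr
        gb = (dv_dr / r)[:, None] * dvec  # dV/dx_j
        np.add.at(grad, self._bj, gb)
        np.add.at(grad, self._bi, -gb)

        if len(self._ai):
            u = x[self._ai] - x[self._aj]
            v = x[self._ak] - x[self._aj]
            ru = np.linalg.norm(u, axis=1)
            rv = np.linalg.norm(v, axis=1)
            c = np.einsum("ij,ij->i", u, v) / (ru * rv)
            dc = c - self._c0
            su = expit(-(ru - self._rs_ij) / self._wsw)
            sv = expit(-(rv - self._rs_jk) / self._wsw)
            vang = self._kt * dc * dc
            energy += float(np.sum(vang * su * sv))

            # chain rule pieces: d(cos)/du, d(cos)/dv, and switch derivatives
            pref = (2.0 * self._kt * dc * su * sv)[:, None]
            dcdu = v / (ru * rv)[:, None] - (c / (ru * ru))[:, None] * u
            dcdv = u / (ru * rv)[:, None] - (c / (rv * rv))[:, None] * v
            dsu = (-su * (1.0 - su) / self._wsw)  # dS/dr
            dsv = (-sv * (1.0 - sv) / self._wsw)
            gu = pref * dcdu + ((vang * dsu * sv) / ru)[:, None] * u
            gv = pref * dcdv + ((vang * su * dsv) / rv)[:, None] * v
            np.add.at(grad, self._ai, gu)
            np.add.at(grad, self._ak, gv)
            np.add.at(grad, self._aj, -(gu + gv))

        return energy + self.offset, grad


def toy_energy_gradient(
    spec: ToyMoleculeSpec, positions: np.ndarray,
    charge_state: Literal["neutral", "cation"] = "neutral",
) -> tuple[float, np.ndarray]:
    """One-shot energy/gradient evaluation of a fixture surface."""
    return ToyPES(spec, charge_state).evaluate(positions)


# ---------------------------------------------------------------------------
# Fragment ionization-potential model
# ---------------------------------------------------------------------------

#: Per-element charge-stabilization score (dimensionless).  Heavier, more
#: polarizable atoms stabilize the cation more, lowering the fragment IP;
#: sulfur dominates, as in the real thiouracils.
_ELEMENT_SCORE = {"S": 3.0, "O": 1.2, "N": 1.8, "C": 1.6, "H": 0.4}

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass
class FragmentIPModel:
    """Deterministic vertical IP for every atom subset of a fixture.

    IP(S) = A − B · s/(s + s0) + γ Σ_{i∈S} ξ_i, where s is the summed
    element score of the subset and ξ_i are fixed per-site offsets (a
    low-discrepancy sequence) that break accidental degeneracies between
    compositionally identical subsets.  A is calibrated so the full atom
    set returns the molecular vertical IP.
    """

    symbols: list[str]
    molecular_ip: float
    b_scale: float = 6.0
    s_half: float = 6.0
    gamma: float = 0.005
    a_base: float = field(init=False)

    def __post_init__(self) -> None:
        full = range(len(self.symbols))
        s = sum(_ELEMENT_SCORE[self.symbols[i]] for i in full)
        xi = sum(self._xi(i) for i in full)
        self.a_base = (
            self.molecular_ip + self.b_scale * s / (s + self.s_half)
            - self.gamma * xi
        )

    @staticmethod
    def _xi(i: int) -> float:
        return ((i + 1) * _GOLDEN) % 1.0 - 0.5

    def ip(self, atom_indices: Iterable[int]) -> float:
        idx = sorted(set(atom_indices))
        if not idx:
            raise ValueError("empty atom index set")
        if idx[0] < 0 or idx[-1] >= len(self.symbols):
            raise IndexError("atom index outside the fixture")
        s = sum(_ELEMENT_SCORE[self.symbols[i]] for i in idx)
        xi = sum(self._xi(i) for i in idx)
        return self.a_base - self.b_scale * s / (s + self.s_half) + self.gamma * xi

    def to_dict(self) -> dict:
        return {
            "molecular_ip_eV": self.molecular_ip,
            "b_scale_eV": self.b_scale,
            "s_half": self.s_half,
            "gamma_eV": self.gamma,
            "element_scores": dict(_ELEMENT_SCORE),
        }


def fragment_ip(model: FragmentIPModel, atom_indices: Iterable[int]) -> float:
    """Vertical IP (eV) of the fragment formed by ``atom_indices``."""
    return model.ip(atom_indices)


# ---------------------------------------------------------------------------
# Fixture construction
# ---------------------------------------------------------------------------

# Atom indices of the fixture, fixed across both variants:
#   0 N1, 1 C2, 2 N3, 3 C4, 4 C5, 5 C6   (six-membered ring, consecutive)
#   6 O, 7 S                              (exocyclic, attachment is the
#                                          variant difference)
#   8 H(N1), 9 H(N3), 10 H(C5), 11 H(C6)
FIXTURE_SYMBOLS = ["N", "C", "N", "C", "C", "C", "O", "S", "H", "H", "H", "H"]

RING = [0, 1, 2, 3, 4, 5]
#: Ring bond (N1–C2) and (N3–C4): the two weakest heavy-atom bonds, whose
#: rupture pair produces the dominant two-fragment channel.
WEAK_CN = [(0, 1), (2, 3)]
MID_CN = [(1, 2), (5, 0)]
RING_CC = [(3, 4), (4, 5)]
H_BONDS = [(0, 8), (2, 9), (4, 10), (5, 11)]

_IP_TARGET = {"2TU-like": 8.73, "4TU-like": 8.54}

# Neutral well depths (eV): ring C–N single bonds are the weakest heavy-atom
# bonds (≈330 kJ/mol) vs ring C–C (≈368 kJ/mol); double bonds and X–H are
# substantially stronger so the ring bonds control fragmentation.
_DE_NEUTRAL = {"weak_cn": 330.0 * KJMOL_TO_EV, "mid_cn": 3.60,
               "ring_cc": 368.0 * KJMOL_TO_EV, "co": 6.0, "cs": 4.8,
               "nh": 4.0, "ch": 4.3}
# Cation well depths (eV): ionization strongly weakens the ring skeleton.
# Ordering is preserved (weak C–N lowest) but the absolute scale drops so
# that 3–7 eV of excess kinetic energy spread over 30 modes fragments the
# ring on a picosecond time scale, as a statistical (RRK-like) rate argument
# requires for a 12-atom system.
_DE_CATION = {"weak_cn": 1.05, "mid_cn": 1.55, "ring_cc": 1.75, "co": 2.6,
              "cs": 2.2, "nh": 3.4, "ch": 3.65}
#: Cation equilibrium-length shift (Å) on the six ring bonds: removing a
#: bonding electron expands the ring.  This shift is what makes the vertical
#: IP geometry dependent (spread ~0.1 eV over a 450 K ensemble).
_CATION_R0_SHIFT = 0.13
_CATION_SHIFTED = ("weak_cn", "mid_cn", "ring_cc")

_MORSE_A = {"heavy": 2.0, "co": 2.2, "cs": 1.8, "xh": 2.2}

_R0 = {"ring": 1.39, "co": 1.22, "cs": 1.65, "nh": 1.01, "ch": 1.08}

_K_ANGLE_HEAVY = 2.5
_K_ANGLE_H = 1.5
_SWITCH_SHIFT = 0.6  # switch midpoint = r0 + shift, Å


def _equilibrium_positions(variant: str) -> np.ndarray:
    """Planar reference geometry: regular hexagon + radial substituents."""
    r_ring = _R0["ring"]  # hexagon side equals circumradius
    pos = np.zeros((12, 3))
    for k in RING:
        th = 2.0 * math.pi * k / 6.0
        pos[k] = [r_ring * math.cos(th), r_ring * math.sin(th), 0.0]
    radial = pos[:6] / r_ring

    def place(idx: int, host: int, dist: float) -> None:
        pos[idx] = pos[host] + radial[host] * dist

    o_host, s_host = (3, 1) if variant == "2TU-like" else (1, 3)
    place(6, o_host, _R0["co"])
    place(7, s_host, _R0["cs"])
    place(8, 0, _R0["nh"])
    place(9, 2, _R0["nh"])
    place(10, 4, _R0["ch"])
    place(11, 5, _R0["ch"])
    return pos


def _bond_class(i: int, j: int, variant: str) -> str:
    pair = tuple(sorted((i, j)))
    if pair in [tuple(sorted(p)) for p in WEAK_CN]:
        return "weak_cn"
    if pair in [tuple(sorted(p)) for p in MID_CN]:
        return "mid_cn"
    if pair in [tuple(sorted(p)) for p in RING_CC]:
        return "ring_cc"
    if 6 in pair:
        return "co"
    if 7 in pair:
        return "cs"
    if pair in [tuple(sorted(p)) for p in H_BONDS]:
        return "nh" if FIXTURE_SYMBOLS[min(pair)] == "N" else "ch"
    raise ValueError(f"unknown bond {pair}")


def _bond_pairs(variant: str) -> list[tuple[int, int]]:
    o_host, s_host = (3, 1) if variant == "2TU-like" else (1, 3)
    ring_bonds = [(RING[k], RING[(k + 1) % 6]) for k in range(6)]
    return ring_bonds + [(o_host, 6), (s_host, 7)] + H_BONDS


def _bond_terms(variant: str, pos: np.ndarray, cation: bool) -> list[BondTerm]:
    table = _DE_CATION if cation else _DE_NEUTRAL
    terms = []
    for i, j in _bond_pairs(variant):
        cls = _bond_class(i, j, variant)
        r0 = float(np.linalg.norm(pos[j] - pos[i]))
        if cation and cls in _CATION_SHIFTED:
            r0 += _CATION_R0_SHIFT
        a = _MORSE_A["xh" if cls in ("nh", "ch") else
                     cls if cls in ("co", "cs") else "heavy"]
        label = f"{FIXTURE_SYMBOLS[i]}{i}-{FIXTURE_SYMBOLS[j]}{j}"
        terms.append(BondTerm(i, j, table[cls], r0, a, label))
    return terms


def _angle_terms(variant: str, pos: np.ndarray,
                 bonds: list[BondTerm]) -> list[AngleTerm]:
    adj: dict[int, list[int]] = {}
    r0_of: dict[tuple[int, int], float] = {}
    for b in bonds:
        adj.setdefault(b.i, []).append(b.j)
        adj.setdefault(b.j, []).append(b.i)
        r0_of[(b.i, b.j)] = r0_of[(b.j, b.i)] = b.r0
    terms = []
    for j, nbrs in sorted(adj.items()):
        nbrs = sorted(nbrs)
        for n1 in range(len(nbrs)):
            for n2 in range(n1 + 1, len(nbrs)):
                i, k = nbrs[n1], nbrs[n2]
                u = pos[i] - pos[j]
                v = pos[k] - pos[j]
                cos0 = float(np.dot(u, v) /
                             (np.linalg.norm(u) * np.linalg.norm(v)))
                light = FIXTURE_SYMBOLS[i] == "H" or FIXTURE_SYMBOLS[k] == "H"
                terms.append(AngleTerm(
                    i, j, k,
                    _K_ANGLE_H if light else _K_ANGLE_HEAVY,
                    cos0,
                    r0_of[(j, i)] + _SWITCH_SHIFT,
                    r0_of[(j, k)] + _SWITCH_SHIFT,
                ))
    return terms


def toy_fixture(
    variant: Literal["2TU-like", "4TU-like"] = "2TU-like",
    seed: int = 0,
) -> tuple[ToyMoleculeSpec, MolecularSystem]:
    """Build a fixture variant and its equilibrium state.

    The two variants share topology and differ only in which ring carbon
    carries the S-analog substituent (position 2 vs position 4).  A tiny
    seeded out-of-plane jitter (1e-4 Å) breaks the exact planarity of the
    reference geometry so that in-plane and out-of-plane motion couple;
    it perturbs the equilibrium energy by < 1e-6 eV.
    """
    if variant not in _IP_TARGET:
        raise ValueError(
            f"unknown variant {variant!r}; expected '2TU-like' or '4TU-like'")
    pos = _equilibrium_positions(variant)
    bonds = _bond_terms(variant, pos, cation=False)
    cation_bonds = _bond_terms(variant, pos, cation=True)
    angles = _angle_terms(variant, pos, bonds)
    ip_model = FragmentIPModel(FIXTURE_SYMBOLS, _IP_TARGET[variant])

    spec = ToyMoleculeSpec(variant, list(FIXTURE_SYMBOLS), bonds, angles,
                           cation_bonds, 0.0, ip_model)
    # Calibrate the constant cation shift so the vertical IP at the
    # reference geometry equals the target exactly.
    e_neutral, _ = ToyPES(spec, "neutral").evaluate(pos)
    e_cation, _ = ToyPES(spec, "cation").evaluate(pos)
    spec.cation_offset = _IP_TARGET[variant] - (e_cation - e_neutral)

    rng = np.random.default_rng(seed)
    jitter = rng.normal(scale=1e-4, size=(12, 3))
    system = MolecularSystem(list(FIXTURE_SYMBOLS), pos + jitter)
    return spec, system
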