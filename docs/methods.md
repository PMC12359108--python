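# Methods

## The model

`photofrag` simulates dissociative photoionization in the sudden, adiabatic
approximation. A closed-shell molecule is thermalized on its neutral
ground-state surface S0; absorption of a VUV photon of energy E_hν ionizes
it vertically, and the excess energy

    E_kin = E_hν − IP(q),     IP(q) = E_D0(q) − E_S0(q)

is assumed to convert entirely into nuclear kinetic energy at the instant of
ionization (no nonadiabatic dynamics; the cation is born and stays in its
ground state D0). The cation then evolves at constant energy until it either
fragments or the simulation window ends. Fragments are the connected
components of the interatomic distance graph with a 4 Å edge criterion; the
single +1 charge is placed by Stevenson's rule on the fragment with the
lowest vertical ionization potential. Counting final-frame cations over an
ensemble of trajectories at each photon energy yields an energy-resolved
mass spectrum and, across the grid, a breakdown diagram.

Assumptions inherited from this approximation, and their consequences:

- instantaneous ionization out of a classical thermal ensemble (no Wigner
  sampling, no Franck–Condon weighting);
- complete statistical redistribution of the excess energy via randomized
  initial velocities — isotropic per-atom Gaussian directions, net linear
  momentum projected out, then a uniform rescale so the deposited kinetic
  energy is exact to machine precision. Net *angular* momentum is not
  removed: spurious overall rotation cannot fragment a molecule, and
  removing it after the rescale would break the exact-energy property.
- the neutral's own thermal kinetic energy, E_ini = (3N−6)/2·kT
  (≈ 0.58 eV for N = 12 at 450 K), is not added to the deposit. When
  comparing with an experimental energy axis, photon energies should be
  shifted down by this amount (12–16 eV → 11.42–15.42 eV); the package
  reports both scales.

Degrees of freedom are 3N − 6 in every temperature formula (kinetic
temperature, thermostat target, thermal-energy correction), consistently.

## The synthetic potential

The electronic-structure engine of a production study is abstracted behind a
minimal contract — `evaluate(positions) → (energy, gradient)` plus a charge
state tag — and the bundled implementation is a reactive bonded potential on
a 12-atom thiouracil-like fixture: a six-membered ring of four carbons and
two nitrogens carrying exocyclic O, S and four hydrogens. The two variants
("2TU-like", "4TU-like") differ only in which ring carbon holds the sulfur.

- **Bonds** are Morse wells, V = D_e(1 − e^{−a(r−r0)})², so they vibrate
  harmonically near equilibrium and dissociate cleanly.
- **Angles** are harmonic in cos θ, multiplied by a sigmoid switching
  function of each flanking bond length (midpoint r0 + 0.6 Å, width
  0.08 Å), so angular stiffness disappears smoothly as a bond breaks and
  the potential remains C¹ everywhere. Torsions are not modelled; the ring
  can pucker freely, which is harmless for fragmentation statistics.
- **Neutral well depths** anchor to literature bond energies for uracil-like
  rings: the two ring C–N single bonds at 330 kJ/mol (3.42 eV) are the
  weakest heavy-atom bonds, ring C–C at 368 kJ/mol (3.81 eV); double bonds
  (C=O 6.0, C=S 4.8 eV) and X–H bonds (4.0–4.3 eV) are stronger.
- **The cation surface** reuses the topology with softened wells — ionization
  removes bonding density — preserving the ordering: weak C–N 1.05 eV,
  mid C–N 1.55, ring C–C 1.75, C=O 2.6, C=S 2.2, N–H 3.4, C–H 3.65 eV. The
  six ring bonds' equilibrium lengths shift +0.13 Å, and a constant offset
  is calibrated at build time so the vertical IP at the equilibrium geometry
  is exactly 8.73 eV (2TU-like) or 8.54 eV (4TU-like). The ring-expansion
  shift is what makes IP(q) geometry dependent: over a 450 K ensemble its
  spread is ≈ 0.10 eV.

The absolute scale of the cation well depths is the one genuinely free
choice, and it was set by a statistical-rate argument: with 3.3–7.3 eV
distributed classically over 30 modes, an RRK-type estimate
k ∝ ν(1 − D_e/E)^{s−1} puts the weakest bond's rupture on the picosecond
time scale only if its effective well depth is near 1 eV. With the values
above, the 12–16 eV photon window spans the entire transition from rare
fragmentation to complete fragmentation — the regime the method is meant to
explore. Because fragmentation of the ring into two pieces requires *two*
ring-bond ruptures, the dominant channel is the double scission of the two
weakest C–N bonds, which for the 2TU-like variant yields the 59 + 69 amu
pair (SCNH + C3NH3O analogs) and for the 4TU-like variant the 43 + 85 amu
pair — the same bonds, different products, purely from the substituent
placement.

A consequence worth stating plainly: at these time scales the photon energy
at which the parent survival probability crosses 50% is *not* IP + min D_e —
entropy delays rupture well past the energetic threshold. The package's
consistency check therefore compares the photon-energy crossing against a
brute-force scan of directly deposited kinetic energy (same pool, same
propagation), which must and does agree within the 0.5 eV grid spacing.

**Fragment IP model.** Stevenson assignment needs a vertical IP for
arbitrary atom subsets, supplied by a deterministic closed form:
IP(S) = A − B·s/(s + s0) + γΣξ_i, where s sums per-element
charge-stabilization scores (S 3.0, N 1.8, C 1.6, O 1.2, H 0.4 — sulfur
dominates, as in the real thiouracils), B = 6 eV, s0 = 6, and ξ_i are fixed
golden-ratio site offsets (γ = 5 meV) that break ties between
compositionally identical subsets. A is calibrated so the full 12-atom set
returns the molecular IP. Larger, more polarizable fragments get lower IPs,
so the 69 amu analog out-competes its 59 amu partner for the charge — the
same outcome the production-level calculations report.

## Dynamics and filtering

Velocity Verlet with dt = 0.5 fs integrates both surfaces; the implementation
is time-reversible to 1e-8 Å over 400 steps and, on bound motion of the
fixture, drifts < 1e-3 eV over 10 ps. NVT sampling uses a simple velocity-
rescaling thermostat applied every 10 steps (a stride avoids over-quenching
fluctuations); snapshots are taken every 100 fs after an equilibration
window. NVE trajectories store every 10th step (5 fs) along with the total
energy. A trajectory is accepted iff max_t |E(t) − E(0)| ≤ 0.1 eV over
stored frames — the absolute-value reading, so negative drifts also reject;
on this smooth surface the filter's acceptance is ~100% and it exists to
honor the protocol, not to discard work. Non-finite energies abort a
trajectory and are counted separately from filter rejections.

Seeding: trajectory i uses seed base_seed XOR i (masked to 31 bits) for both
its snapshot draw and its deposition velocities. The same draws are reused
across photon energies — common random numbers, which reduces the variance
of breakdown-curve differences; energies differ only through E_hν − IP.
Below-threshold events (E_hν < IP at the drawn geometry) are not propagated
and count the parent as intact.

## Analysis conventions

- Fragment identity is the exact atom-index set, not the formula, so
  isobars (CO at 28.01 vs HCNH at 28.03 amu) and even same-formula
  fragments with different atoms stay distinct records.
- Masses use average atomic weights (H 1.008, C 12.011, N 14.007, O 15.999,
  S 32.06); two-decimal labels disambiguate isobars, nearest-integer bins
  define m/z. This convention reproduces every printed integer label of the
  reference fragment set.
- Abundances follow F_i = N_i/Σ_j N_j. All-fragments mode counts every
  surviving final-frame fragment, the intact parent included; cations-only
  mode counts each accepted trajectory's final cation, so its denominator
  equals the accepted-trajectory count and the table is a mass spectrum.
  Transient fragments (separated beyond 4 Å, later recombined, or
  superseded by further fragmentation) are excluded from abundance counts
  but appear in the first-occurrence tree and inventories.
- Bond events use hysteresis: break at r > 1.8·r0, re-form at r < 1.3·r0,
  each sustained for a 50 fs dwell window; events are stamped at window
  start. H-transfer is a persistent change of a hydrogen's nearest heavy
  neighbor. Dissociation time is the first stored-frame time after which
  the 4 Å partition never returns to one piece; ensemble means run over
  fragmenting trajectories only. All three thresholds are configuration
  knobs; defaults were chosen to suppress vibrational flicker (bond
  amplitude at these temperatures is ≪ 0.8·r0) while catching every real
  rupture — every 4 Å fragmentation is preceded by a threshold break event
  by construction, since 1.8·r0 < 4 Å for all bonds here.

## What the synthetic data does and does not emulate

The toy surface reproduces the *structure* of the problem: a calibrated and
geometry-dependent vertical IP, weakest-bond selectivity, multi-step
fragmentation with transients and recombination, isobaric products,
Stevenson charge competition, and the qualitative energy laws (threshold
behavior, monotone fragmentation fraction, decreasing dissociation times,
secondary fragmentation of the primary product at high energy). It does not
reproduce real thiouracil energetics: no tautomers, no excited cation
states, no H-loss fine structure, no quantitative abundances or crossing
energies — a toy crossing near 12.5 eV says nothing about the production
value near 13.8 eV beyond the shape of the curves. Passing tests validate
the pipeline's mechanics and bookkeeping, not thiouracil chemistry.

## Problem sizes

Defaults mirror the reference protocol (450 K, 100 ps NVT, 10 ps NVE,
0.5 fs, 12–16 eV in 0.5 eV steps, 4 Å, 0.1 eV filter); trajectory counts
default to a desk-scale 50 per energy (1000 in the reference protocol).
The test suite and the acceptance script use reduced, fully seeded
conditions — 6 ps NVT pools, 2 ps NVE windows, 60–100 trajectories per
energy — sizes at which every ensemble statistic asserted is well resolved
(binomial allowance is built into the monotonicity test). The tiny
end-to-end campaign (2 energies × 10 trajectories × 2 ps) completes in well
under two minutes on one CPU.

## Numerical choices

- Unit system Å / fs / amu / eV; the single mechanical conversion constant
  is 1 amu·Å²/fs² = 103.6427 eV (CODATA-derived), k_B = 8.617333e-5 eV/K.
- Analytic gradients throughout (verified against central differences to
  1e-6 eV/Å); the switching sigmoid uses `scipy.special.expit` to avoid
  overflow at large separations.
- Charge-assignment tie-breaks: lower IP, then larger fragment mass, then
  smaller lowest atom index — total order, so assignment is deterministic.
- The equilibrium fixture carries a seeded 1e-4 Å out-of-plane jitter to
  break exact planarity (the reference geometry is a critical point of the
  planar symmetry); it perturbs energies by < 1e-6 eV.
- Degenerate inputs: empty atom sets, empty partitions, zero-KE rescaling
  to finite temperature, all-zero abundance counts, and malformed XYZ
  frames all raise `ValueError` with specific messages rather than
  propagating NaNs.
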