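"""Integrator correctness (free particle, analytic harmonic oracle,
symplectic drift, time reversibility), thermostat and the energy filter."""

import numpy as np
import pytest

from photofrag.chem import EV_TO_KE, MolecularSystem
from photofrag.md import (Trajectory, energy_conservation_filter,
                          instantaneous_temperature, propagate_nve,
                          propagate_nvt, rescale_velocities,
                          trajectory_from_xyz, velocity_verlet_step)
from photofrag.toy_pes import ToyPES
from photofrag.ionization import sample_deposition_velocities


def _single_atom(mass_symbol="C", x=0.0, v=0.0):
    return MolecularSystem([mass_symbol], np.array([[x, 0.0, 0.0]]),
                           np.array([[v, 0.0, 0.0]]))


def test_free_particle_drifts_linearly(constant_pes):
    system = _single_atom(x=1.0, v=0.25)
    out, _, _ = velocity_verlet_step(system, constant_pes(), dt=2.0)
    assert out.positions[0, 0] == pytest.approx(1.5)
    assert out.velocities[0, 0] == pytest.approx(0.25)


def test_harmonic_oscillator_matches_cosine(harmonic_pes):
    """1000 velocity-Verlet steps across one period vs x(t) = A cos ωt."""
    k, mass = 5.0, 12.011
    omega = np.sqrt(k * EV_TO_KE / mass)  # rad/fs
    period = 2 * np.pi / omega
    dt = period / 1000.0
    amplitude = 0.1
    system = _single_atom(x=amplitude)
    pes = harmonic_pes(k)
    gradient = None
    worst = 0.0
    for step in range(1, 1001):
        system, _, gradient = velocity_verlet_step(system, pes, dt, gradient)
        exact = amplitude * np.cos(omega * step * dt)
        worst = max(worst, abs(system.positions[0, 0] - exact))
    assert worst < 1e-3 * amplitude


def test_harmonic_energy_drift_is_bounded(harmonic_pes):
    """Symplectic integration: |E(t) − E(0)| stays tiny over 20,000 steps."""
    k, amplitude = 5.0, 0.1
    system = _single_atom(x=amplitude)
    pes = harmonic_pes(k)
    traj = propagate_nve(system, pes, duration=10_000.0, dt=0.5,
                         sample_stride=10)
    assert np.abs(traj.energies - traj.energies[0]).max() < 1e-4


def test_velocity_verlet_time_reversible(fixture_2tu):
    spec, eq = fixture_2tu
    pes = ToyPES(spec, "neutral")
    state = eq.copy()
    state.velocities = sample_deposition_velocities(state.masses, 0.5, 9)
    x0 = state.positions.copy()
    gradient = None
    for _ in range(400):
        state, _, gradient = velocity_verlet_step(state, pes, 0.5, gradient)
    state.velocities *= -1.0
    gradient = None
    for _ in range(400):
        state, _, gradient = velocity_verlet_step(state, pes, 0.5, gradient)
    assert np.abs(state.positions - x0).max() < 1e-8


class TestRescale:
    def _thermal_state(self, t_kelvin):
        rng = np.random.default_rng(0)
        system = MolecularSystem(["C", "N", "O", "S"], np.zeros((4, 3)),
                                 rng.normal(scale=0.005, size=(4, 3)))
        return rescale_velocities(system, t_kelvin)

    def test_doubling_temperature_doubles_ke(self):
        from photofrag.chem import kinetic_energy

        state = self._thermal_state(225.0)
        hot = rescale_velocities(state, 450.0)
        assert kinetic_energy(hot) == pytest.approx(
            2.0 * kinetic_energy(state), rel=1e-12)

    def test_identity_at_current_temperature(self):
        state = self._thermal_state(300.0)
        same = rescale_velocities(state, instantaneous_temperature(state))
        assert np.allclose(same.velocities, state.velocities, rtol=1e-12)

    def test_idempotent_after_first_application(self):
        state = self._thermal_state(123.0)
        once = rescale_velocities(state, 450.0)
        twice = rescale_velocities(once, 450.0)
        assert np.allclose(once.velocities, twice.velocities, rtol=1e-12)

    def test_zero_ke_cannot_reach_finite_t(self):
        system = MolecularSystem(["C"], np.zeros((1, 3)))
        with pytest.raises(ValueError):
            rescale_velocities(system, 300.0)


class TestNVT:
    def test_snapshot_count_from_strides(self, fixture_2tu):
        spec, eq = fixture_2tu
        pes = ToyPES(spec, "neutral")
        snaps = propagate_nvt(eq, pes, 450.0, duration=2000.0, dt=0.5,
                              sample_stride=200, seed=3)
        assert len(snaps) == 20  # 2 ps / 100 fs

    def test_same_seed_reproduces_snapshots(self, fixture_2tu):
        spec, eq = fixture_2tu
        pes = ToyPES(spec, "neutral")
        a = propagate_nvt(eq, pes, 450.0, 1000.0, dt=0.5,
                          sample_stride=100, seed=11)
        b = propagate_nvt(eq, pes, 450.0, 1000.0, dt=0.5,
                          sample_stride=100, seed=11)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.positions, sb.positions)
            assert np.array_equal(sa.velocities, sb.velocities)

    def test_cold_start_converges_to_target_temperature(self, fixture_2tu):
        """Starting from T = 0 the thermostat injects energy until the
        time-averaged temperature tracks the target within 5%."""
        spec, eq = fixture_2tu
        pes = ToyPES(spec, "neutral")
        snaps = propagate_nvt(eq, pes, 450.0, duration=6000.0, dt=0.5,
                              sample_stride=20, seed=5,
                              equilibration=1000.0)
        temps = [instantaneous_temperature(s) for s in snaps]
        assert np.mean(temps) == pytest.approx(450.0, rel=0.05)


class TestNVE:
    def test_frame_count_arithmetic(self, harmonic_pes):
        system = _single_atom(x=0.05)
        traj = propagate_nve(system, harmonic_pes(5.0), duration=10_000.0,
                             dt=0.5, sample_stride=10)
        assert traj.n_frames == 2001
        assert np.allclose(np.diff(traj.times), 5.0)

    def test_bound_motion_energy_flat(self, fixture_2tu):
        spec, eq = fixture_2tu
        pes = ToyPES(spec, "neutral")
        state = eq.copy()
        state.velocities = sample_deposition_velocities(state.masses, 0.25, 5)
        traj = propagate_nve(state, pes, 10_000.0, dt=0.5, sample_stride=10)
        assert np.abs(traj.energies - traj.energies[0]).max() < 1e-3
        assert energy_conservation_filter(traj)

    def test_fragments_separate_monotonically_after_break(self, fixture_2tu):
        """With KE far above every well depth the molecule flies apart and
        inter-fragment distances grow monotonically."""
        spec, eq = fixture_2tu
        pes = ToyPES(spec, "cation")
        state = eq.copy()
        state.velocities = sample_deposition_velocities(
            state.masses, 60.0, 12)
        traj = propagate_nve(state, pes, 400.0, dt=0.5, sample_stride=10)
        from photofrag.fragments import detect_fragments

        final = detect_fragments(traj.positions[-1], 4.0)
        assert len(final) > 1
        a, b = final[0], final[1]
        seps = [
            np.linalg.norm(traj.positions[k][list(a)].mean(axis=0)
                           - traj.positions[k][list(b)].mean(axis=0))
            for k in range(traj.n_frames - 20, traj.n_frames)
        ]
        assert all(x < y for x, y in zip(seps, seps[1:]))


class TestEnergyFilter:
    def _traj(self, energies):
        n = len(energies)
        return Trajectory(np.arange(n, dtype=float), np.zeros((n, 1, 3)),
                          np.zeros((n, 1, 3)), np.asarray(energies, float),
                          ["C"], np.array([12.011]))

    def test_flat_trace_accepted(self):
        assert energy_conservation_filter(self._traj([1.0] * 5))

    def test_excursion_rejected(self):
        assert not energy_conservation_filter(
            self._traj([1.0, 1.2, 1.0, 1.0]))

    def test_bound_is_inclusive(self):
        # deviation is exactly the 0.1 eV tolerance → still accepted
        assert energy_conservation_filter(self._traj([0.0, 0.1, 0.0]))

    def test_negative_drift_counts(self):
        assert not energy_conservation_filter(self._traj([1.0, 0.85, 1.0]))

    def test_aborted_never_accepted(self):
        traj = self._traj([1.0, 1.0])
        traj.aborted = True
        assert not energy_conservation_filter(traj)


def test_trajectory_xyz_round_trip(tmp_path, fixture_2tu):
    spec, eq = fixture_2tu
    pes = ToyPES(spec, "neutral")
    state = eq.copy()
    state.velocities = sample_deposition_velocities(state.masses, 0.2, 1)
    traj = propagate_nve(state, pes, 50.0, dt=0.5, sample_stride=10,
                         metadata={"E_hv_eV": 13.0, "seed": 1})
    path = tmp_path / "traj.xyz"
    traj.to_xyz(path)
    back = trajectory_from_xyz(path)
    assert back.n_frames == traj.n_frames
    assert np.allclose(back.times, traj.times)
    assert np.allclose(back.positions, traj.positions, atol=1e-11)
    assert np.allclose(back.energies, traj.energies, atol=1e-7)
    assert back.metadata["E_hv_eV"] == pytest.approx(13.0)
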