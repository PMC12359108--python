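"""Bond-event detection with hysteresis, hydrogen-transfer assignment,
dissociation-time statistics and mechanism signatures — on scripted
trajectories with known event content."""

import numpy as np
import pytest

from photofrag.chem import ATOMIC_WEIGHTS
from photofrag.md import Trajectory
from photofrag.mechanisms import (bond_event_timeline, detect_h_transfer,
                                  dissociation_time, mean_dissociation_time,
                                  mechanism_signature, tally_signatures)


def scripted(frames, symbols, dt=5.0):
    pos = np.array(frames, dtype=float)
    n = len(frames)
    masses = np.array([ATOMIC_WEIGHTS[s] for s in symbols])
    return Trajectory(np.arange(n) * dt, pos, np.zeros_like(pos),
                      np.zeros(n), list(symbols), masses)


def _linear(*xs):
    return np.array([[x, 0.0, 0.0] for x in xs])


def _ramp_frames(n_frames, start, end, hold=0):
    """Two atoms, one fixed, the other ramping from start to end Å."""
    xs = np.linspace(start, end, n_frames - hold)
    xs = np.concatenate([xs, np.full(hold, end)])
    return [_linear(0.0, x) for x in xs]


BOND = [(0, 1, 1.4)]  # reference C–N-like bond with r0 = 1.4 Å


class TestBondEvents:
    def test_single_ramp_gives_one_break(self):
        traj = scripted(_ramp_frames(40, 1.4, 6.0), ["C", "N"])
        events = bond_event_timeline(traj, BOND, dwell_fs=50.0,
                                     watch_new_contacts=False)
        breaks = [e for e in events if e.kind == "break"]
        assert len(breaks) == 1
        assert breaks[0].atoms == (0, 1)

    def test_brief_excursion_below_dwell_is_ignored(self):
        # cross the 1.8·r0 = 2.52 Å threshold for 2 frames (10 fs) only
        frames = [_linear(0.0, 1.4)] * 10 + [_linear(0.0, 3.0)] * 2 \
            + [_linear(0.0, 1.4)] * 10
        traj = scripted(frames, ["C", "N"])
        events = bond_event_timeline(traj, BOND, dwell_fs=50.0,
                                     watch_new_contacts=False)
        assert events == []

    def test_event_timestamp_is_window_start(self):
        frames = [_linear(0.0, 1.4)] * 10 + [_linear(0.0, 6.0)] * 30
        traj = scripted(frames, ["C", "N"])
        events = bond_event_timeline(traj, BOND, dwell_fs=50.0,
                                     watch_new_contacts=False)
        assert events[0].time_fs == pytest.approx(50.0)  # frame 10 at 5 fs

    def test_break_then_reform(self):
        frames = ([_linear(0.0, 1.4)] * 5 + [_linear(0.0, 6.0)] * 20
                  + [_linear(0.0, 1.4)] * 20)
        traj = scripted(frames, ["C", "N"])
        events = bond_event_timeline(traj, BOND, dwell_fs=50.0,
                                     watch_new_contacts=False)
        assert [e.kind for e in events] == ["break", "form"]
        assert events[0].time_fs < events[1].time_fs

    def test_new_contact_formation_watched(self):
        # S (atom 2) approaches C (atom 0) and stays bonded
        frames = [np.array([[0.0, 0, 0], [1.4, 0, 0], [8.0, 0, 0]])] * 5 \
            + [np.array([[0.0, 0, 0], [1.4, 0, 0], [1.7, 0, 0]])] * 30
        traj = scripted(frames, ["C", "N", "S"])
        events = bond_event_timeline(traj, BOND, dwell_fs=50.0)
        forms = [e for e in events if e.kind == "form"]
        assert any(set(e.atoms) == {0, 2} for e in forms)

    def test_stride_refinement_preserves_event_order(self):
        frames = ([_linear(0.0, 1.4, 2.8)] * 10
                  + [_linear(0.0, 6.0, 7.4)] * 20      # break 0–1 first
                  + [_linear(0.0, 6.0, 30.0)] * 20)    # then 1–2
        bonds = [(0, 1, 1.4), (1, 2, 1.4)]
        coarse = scripted(frames, ["C", "N", "C"], dt=5.0)
        fine_frames = [f for f in frames for _ in range(2)]
        fine = scripted(fine_frames, ["C", "N", "C"], dt=2.5)
        ev_coarse = bond_event_timeline(coarse, bonds, dwell_fs=50.0,
                                        watch_new_contacts=False)
        ev_fine = bond_event_timeline(fine, bonds, dwell_fs=50.0,
                                      watch_new_contacts=False)
        assert [(e.kind, e.atoms) for e in ev_coarse] == \
            [(e.kind, e.atoms) for e in ev_fine]


class TestHTransfer:
    def _frames(self, h_positions):
        # heavy atoms: N at origin, S at x = 3 Å; H migrates between them
        return [np.array([[0.0, 0, 0], [3.0, 0, 0], [x, 0.5, 0]])
                for x in h_positions]

    def test_persistent_transfer_detected(self):
        frames = self._frames([0.5] * 5 + [2.6] * 30)
        traj = scripted(frames, ["N", "S", "H"])
        events = detect_h_transfer(traj, dwell_fs=50.0)
        assert len(events) == 1
        ev = events[0]
        assert ev.kind == "H-transfer"
        assert ev.donor == 0 and ev.acceptor == 1

    def test_vibration_about_one_neighbor_ignored(self):
        frames = self._frames([0.4, 0.6, 0.5, 0.7, 0.4, 0.6] * 6)
        traj = scripted(frames, ["N", "S", "H"])
        assert detect_h_transfer(traj, dwell_fs=50.0) == []

    def test_back_and_forth_gives_two_ordered_events(self):
        frames = self._frames([0.5] * 5 + [2.6] * 20 + [0.5] * 20)
        traj = scripted(frames, ["N", "S", "H"])
        events = detect_h_transfer(traj, dwell_fs=50.0)
        assert [(e.donor, e.acceptor) for e in events] == [(0, 1), (1, 0)]
        assert events[0].time_fs < events[1].time_fs


class TestDissociationTime:
    def test_non_fragmenting_returns_none(self):
        traj = scripted([_linear(0.0, 1.4)] * 10, ["C", "N"])
        assert dissociation_time(traj) is None

    def test_split_without_recombination(self):
        frames = [_linear(0.0, 1.4)] * 4 + [_linear(0.0, 9.0)] * 6
        traj = scripted(frames, ["C", "N"])
        assert dissociation_time(traj) == pytest.approx(20.0)  # frame 4

    def test_transient_separation_not_counted(self):
        frames = ([_linear(0.0, 1.4)] * 3 + [_linear(0.0, 9.0)] * 3
                  + [_linear(0.0, 1.4)] * 3 + [_linear(0.0, 9.0)] * 3)
        traj = scripted(frames, ["C", "N"])
        assert dissociation_time(traj) == pytest.approx(9 * 5.0)

    def test_dissociation_never_precedes_first_break(self, fixture_2tu):
        """4 Å separation must come after the 1.8·r0 threshold crossing."""
        from photofrag.ionization import run_ensemble

        spec, eq = fixture_2tu
        res = run_ensemble(spec, eq, [15.0], n_trajectories=8,
                           nvt_duration=1000.0, nve_duration=800.0,
                           base_seed=13)[15.0]
        checked = 0
        for traj in res.trajectories:
            t_diss = dissociation_time(traj)
            if t_diss is None:
                continue
            breaks = [e for e in bond_event_timeline(
                traj, spec.bonds, watch_new_contacts=False)
                if e.kind == "break"]
            assert breaks and min(e.time_fs for e in breaks) <= t_diss
            checked += 1
        assert checked > 0

    def test_mean_over_fragmenting_only(self):
        frag = scripted([_linear(0.0, 1.4)] * 2 + [_linear(0.0, 9.0)] * 4,
                        ["C", "N"])
        whole = scripted([_linear(0.0, 1.4)] * 6, ["C", "N"])
        assert mean_dissociation_time([frag, whole]) == pytest.approx(10.0)
        assert np.isnan(mean_dissociation_time([whole]))


class TestSignatures:
    def _two_break_trajectory(self):
        # bond 0–1 breaks first (atoms stay inside the 4 Å criterion, like
        # a ring opening), then 2–3 breaks and the pieces fly apart
        sym = ["N", "C", "N", "C"]
        f0 = _linear(0.0, 1.4, 2.8, 4.2)
        f1 = _linear(-2.6, 1.4, 2.8, 4.2)    # 0–1 at 4.0 Å: broken, attached
        f2 = _linear(-20.0, 1.4, 2.8, 12.0)  # then break 2–3, dissociation
        frames = [f0] * 5 + [f1] * 20 + [f2] * 20
        bonds = [(0, 1, 1.4), (1, 2, 1.4), (2, 3, 1.4)]
        return scripted(frames, sym), bonds

    def test_ordered_two_break_signature(self):
        traj, bonds = self._two_break_trajectory()
        sig = mechanism_signature(traj, bonds, include_h_transfer=False)
        kinds = [(e.kind, e.atoms) for e in sig.events]
        assert kinds == [("break", (0, 1)), ("break", (2, 3))]
        assert sig.final_formulas == ("C", "CN", "N")

    def test_identical_trajectories_identical_signatures(self):
        traj, bonds = self._two_break_trajectory()
        s1 = mechanism_signature(traj, bonds).key
        s2 = mechanism_signature(traj, bonds).key
        assert s1 == s2

    def test_tally_counts_repeats(self):
        traj, bonds = self._two_break_trajectory()
        tally = tally_signatures([traj, traj, traj], bonds)
        assert list(tally.values()) == [3]

    def test_signature_key_readable(self):
        traj, bonds = self._two_break_trajectory()
        key = mechanism_signature(traj, bonds,
                                  include_h_transfer=False).key
        assert "break(N0-C1)" in key and "break(N2-C3)" in key
        assert key.endswith("C+CN+N")
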