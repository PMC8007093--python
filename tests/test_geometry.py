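"""Dihedrals, pseudorotation, Cremer-Pople coordinates and CV tables."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voapipe.geometry import (
    CVTable,
    DegenerateGeometryError,
    Frame,
    PuckerPhaseCV,
    RingDefinition,
    RingPhaseCV,
    TorsionCV,
    Trajectory,
    cremer_pople,
    cv_timeseries,
    dihedral,
    pseudorotation,
    ring_pseudorotation,
    ring_torsions,
    wrap_angle,
)
from voapipe.synth import MONOMER_RING, PlantedState, make_dimer_frame, make_ring_geometry, make_trajectory
from voapipe.synth import DIMER_PSEUDO_RING, DIMER_RING_A, DIMER_RING_B


def dihedral_oracle(p1, p2, p3, p4):
    """Independent dihedral: project bonds off the central axis, atan2."""
    p1, p2, p3, p4 = map(np.asarray, (p1, p2, p3, p4))
    b0, b1, b2 = p1 - p2, p3 - p2, p4 - p3
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - b0.dot(b1) * b1
    w = b2 - b2.dot(b1) * b1
    return math.degrees(math.atan2(np.cross(b1, v).dot(w), v.dot(w)))


def hexagon_frame(z, radius=1.4):
    ang = 2 * np.pi * np.arange(6) / 6
    pos = np.c_[radius * np.cos(ang), radius * np.sin(ang), z]
    return Frame(labels=["C"] * 6, coords=pos, mol_ids=np.zeros(6, int))


HEX_RING = RingDefinition(atoms=(1, 2, 3, 4, 5, 6))


class TestDihedral:
    def test_planar_zigzag_is_anti(self):
        assert dihedral((0, 0, 1), (0, 0, 0), (1, 0, 0), (1, 0, -1)) == pytest.approx(180.0)

    def test_orthogonal_case_sign_convention(self):
        # clockwise-positive looking from atom 2 to atom 3
        assert dihedral((0, 0, 1), (0, 0, 0), (1, 0, 0), (1, 1, 0)) == pytest.approx(-90.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=12, max_size=12))
    def test_agrees_with_independent_oracle(self, flat):
        pts = np.array(flat).reshape(4, 3)
        try:
            d = dihedral(*pts)
        except DegenerateGeometryError:
            return
        assert abs(wrap_angle(d - dihedral_oracle(*pts))) < 1e-9

    @pytest.mark.parametrize(
        "pts",
        [
            [(0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)],  # zero bond
            [(2, 0, 0), (1, 0, 0), (0, 0, 0), (0, 1, 0)],  # collinear 1-2-3
        ],
    )
    def test_degenerate_geometry_raises(self, pts):
        with pytest.raises(DegenerateGeometryError):
            dihedral(*pts)


class TestRingTorsions:
    def test_planar_pentagon_all_zero(self):
        frame = make_ring_geometry(0.0, 0.0)
        assert np.allclose(ring_torsions(frame, MONOMER_RING), 0.0, atol=1e-9)

    def test_round_trip_against_builder(self):
        frame = make_ring_geometry(-60.0, 35.0)
        nu = ring_torsions(frame, MONOMER_RING)
        state = pseudorotation(nu[1], nu[3])
        assert abs(wrap_angle(state.P_theta + 60.0)) < 1e-3
        assert state.A_r == pytest.approx(35.0, abs=1e-3)

    def test_cyclic_relabeling_rotates_torsion_list(self):
        frame = make_ring_geometry(40.0, 30.0)
        nu = ring_torsions(frame, MONOMER_RING)
        shifted = ring_torsions(frame, RingDefinition(atoms=(2, 3, 4, 5, 1)))
        assert np.allclose(shifted, np.roll(nu, -1), atol=1e-9)


class TestPseudorotation:
    def test_planar_ring_phase_undefined(self):
        state = pseudorotation(0.0, 0.0)
        assert state.A_r == 0.0 and state.P_theta is None

    def test_enantiomer_shifts_phase_by_180(self):
        a = pseudorotation(25.0, -30.0)
        b = pseudorotation(-25.0, 30.0)
        assert b.A_r == pytest.approx(a.A_r)
        assert abs(abs(wrap_angle(b.P_theta - a.P_theta)) - 180.0) < 1e-9

    @pytest.mark.parametrize("planted", range(-165, 181, 15))
    def test_planted_phase_recovered(self, planted):
        frame = make_ring_geometry(float(planted), 40.0)
        state = ring_pseudorotation(frame, MONOMER_RING)
        assert abs(wrap_angle(state.P_theta - planted)) < 1.0

    def test_phase_shifts_144_under_relabeling_cosine_model(self):
        # exact on torsions that follow the cosine wave nu_j = A cos(P + 144 j):
        # relabelling by one atom maps (nu1, nu3) -> (nu2, nu4), i.e. P -> P + 144
        a, p = 40.0, 10.0
        nu = [a * math.cos(math.radians(p + 144.0 * j)) for j in range(5)]
        base = pseudorotation(nu[1], nu[3])
        shifted = pseudorotation(nu[2], nu[4])
        assert shifted.A_r == pytest.approx(base.A_r, abs=1e-9)
        assert abs(wrap_angle(shifted.P_theta - base.P_theta - 144.0)) < 1e-9

    def test_relabeling_on_real_ring_approximately_invariant(self):
        # a geometric ring carries small higher harmonics, so the two-torsion
        # amplitude is only approximately labeling-invariant
        frame = make_ring_geometry(10.0, 40.0)
        base = ring_pseudorotation(frame, MONOMER_RING)
        shifted = ring_pseudorotation(frame, RingDefinition(atoms=(2, 3, 4, 5, 1)))
        assert shifted.A_r == pytest.approx(base.A_r, rel=0.05)
        delta = wrap_angle(shifted.P_theta - base.P_theta)
        assert abs(wrap_angle(delta - 144.0)) < 3.0

    def test_rigid_motion_invariance(self, rng):
        frame = make_ring_geometry(-100.0, 38.0)
        base = ring_pseudorotation(frame, MONOMER_RING)
        # random proper rotation + translation
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = Frame(
            labels=frame.labels,
            coords=frame.coords @ q.T + rng.normal(size=3) * 10,
            mol_ids=frame.mol_ids,
        )
        st2 = ring_pseudorotation(moved, MONOMER_RING)
        assert st2.A_r == pytest.approx(base.A_r, abs=1e-9)
        assert abs(wrap_angle(st2.P_theta - base.P_theta)) < 1e-9

    def test_mirror_symmetry(self):
        frame = make_ring_geometry(50.0, 35.0)
        base = ring_pseudorotation(frame, MONOMER_RING)
        mirrored = Frame(
            labels=frame.labels, coords=frame.coords * [1, 1, -1], mol_ids=frame.mol_ids
        )
        st2 = ring_pseudorotation(mirrored, MONOMER_RING)
        assert st2.A_r == pytest.approx(base.A_r, abs=1e-9)
        assert abs(abs(wrap_angle(st2.P_theta - base.P_theta)) - 180.0) < 1e-9


def cp6(frame, **kw):
    """Cremer-Pople on the standard hexagon helper ring."""
    return cremer_pople(frame, HEX_RING, **kw)


class TestCremerPople:
    def test_planar_hexagon_amplitudes_zero(self):
        state = cp6(hexagon_frame(np.zeros(6)))
        assert state.q2 == pytest.approx(0.0, abs=1e-12)
        assert state.q3 == pytest.approx(0.0, abs=1e-12)
        assert state.phi is None

    def test_ideal_chair_is_pure_q3(self):
        state = cp6(hexagon_frame(0.25 * np.array([1.0, -1, 1, -1, 1, -1])))
        assert state.q2 == pytest.approx(0.0, abs=1e-12)
        assert abs(state.q3) > 0.5
        assert state.Q == pytest.approx(math.hypot(state.q2, state.q3), abs=1e-12)

    @pytest.mark.parametrize("phi0", [0.0, -64.0, 90.0, 137.0, -180.0])
    def test_planted_phase_recovered(self, phi0):
        ang = 2 * np.pi * np.arange(6) / 6
        state = cp6(hexagon_frame(0.3 * np.cos(2 * ang + math.radians(phi0))))
        assert abs(wrap_angle(state.phi - phi0)) < 0.5

    def test_rigid_motion_invariance(self, rng):
        ang = 2 * np.pi * np.arange(6) / 6
        frame = hexagon_frame(0.3 * np.cos(2 * ang + 1.0))
        base = cp6(frame)
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = Frame(labels=frame.labels, coords=frame.coords @ q.T + 5.0, mol_ids=frame.mol_ids)
        st2 = cp6(moved)
        assert st2.q2 == pytest.approx(base.q2, abs=1e-9)
        assert abs(st2.q3) == pytest.approx(abs(base.q3), abs=1e-9)

    def test_degenerate_ring_raises(self):
        pos = np.zeros((6, 3))
        pos[:, 0] = np.arange(6)  # collinear
        frame = Frame(labels=["C"] * 6, coords=pos, mol_ids=np.zeros(6, int))
        with pytest.raises(DegenerateGeometryError):
            cp6(frame)


class TestCVTimeseries:
    def test_static_trajectory_constant_columns(self):
        frame = make_ring_geometry(-157.0, 42.0, oh_torsion=80.0)
        traj = Trajectory.from_frames([frame] * 5)
        table = cv_timeseries(
            traj,
            [
                PuckerPhaseCV(name="P_theta", ring=MONOMER_RING),
                TorsionCV(name="oh_torsion", atoms=(7, 6, 2, 1)),
            ],
        )
        assert (table.values.nunique() == 1).all()
        assert table.values["oh_torsion"].iloc[0] == pytest.approx(80.0, abs=1e-6)

    def test_planted_state_means_recovered(self):
        states = [PlantedState(means=(-157.3, 81.2), kappas=(80.0, 80.0), weight=1.0)]
        traj, _ = make_trajectory(states, 250, seed=7)
        table = cv_timeseries(
            traj,
            [
                PuckerPhaseCV(name="P_theta", ring=MONOMER_RING),
                TorsionCV(name="oh_torsion", atoms=(7, 6, 2, 1)),
            ],
        )
        # von Mises kappa=80 -> circular sd ~6.4 deg; mean of 250 within ~3 se
        from voapipe.clustering import circular_mean

        assert abs(wrap_angle(circular_mean(table.values["P_theta"]) + 157.3)) < 1.5
        assert abs(wrap_angle(circular_mean(table.values["oh_torsion"]) - 81.2)) < 1.5

    def test_dimer_trajectory_three_phase_columns(self):
        frames = [make_dimer_frame(-157.0, 20.0, -64.0, frame_index=i) for i in range(3)]
        traj = Trajectory.from_frames(frames)
        table = cv_timeseries(
            traj,
            [
                PuckerPhaseCV(name="P_thetaA", ring=DIMER_RING_A),
                PuckerPhaseCV(name="P_thetaB", ring=DIMER_RING_B),
                RingPhaseCV(name="phi", ring=DIMER_PSEUDO_RING),
            ],
        )
        assert table.names == ["P_thetaA", "P_thetaB", "phi"]
        assert table.values["phi"].iloc[0] == pytest.approx(-64.0, abs=2.0)

    def test_topology_mismatch_names_offending_cv(self):
        traj = Trajectory.from_frames([make_ring_geometry(0.0, 30.0)])  # 5 atoms only
        with pytest.raises(ValueError, match="oh_torsion"):
            cv_timeseries(traj, [TorsionCV(name="oh_torsion", atoms=(7, 6, 2, 1))])

    def test_csv_round_trip(self, tmp_path):
        states = [PlantedState(means=(10.0, 20.0), kappas=(30.0, 30.0), weight=1.0)]
        traj, _ = make_trajectory(states, 10, seed=1)
        table = cv_timeseries(
            traj,
            [
                PuckerPhaseCV(name="P_theta", ring=MONOMER_RING),
                TorsionCV(name="oh_torsion", atoms=(7, 6, 2, 1)),
            ],
        )
        path = tmp_path / "cvs.csv"
        table.to_csv(path)
        back = CVTable.from_csv(path)
        assert np.allclose(back.values.to_numpy(), table.values.to_numpy(), atol=1e-6)
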