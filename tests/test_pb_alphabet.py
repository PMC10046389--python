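"""Dihedral computation and Protein Blocks assignment."""

import biotite.structure as struc
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pbtraj import (
    PB_LABELS,
    assign_pbs,
    compute_phi_psi,
    dihedral,
    rmsda,
    trajectory_from_dihedrals,
    wrap_degrees,
)
from pbtraj.pb import PB_MATRIX, dihedral_windows
from pbtraj.trajectory import Trajectory


def test_dihedral_planar_anti_is_180():
    ang = dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0])
    assert ang == pytest.approx(180.0)


def test_dihedral_right_angle_sign():
    # +90 rotation about the central bond under the IUPAC convention
    ang = dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 0, 1])
    assert abs(abs(ang) - 90.0) < 1e-12


def test_mirror_negates_dihedrals():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(20, 4, 3))
    d = dihedral(pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3])
    mirrored = pts * np.array([1.0, 1.0, -1.0])
    dm = dihedral(mirrored[:, 0], mirrored[:, 1], mirrored[:, 2], mirrored[:, 3])
    assert np.allclose(dm, -d, atol=1e-9)


def test_dihedral_matches_biotite():
    rng = np.random.default_rng(2)
    pts = rng.normal(size=(50, 4, 3)) * 3
    ours = dihedral(pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3])
    ref = np.degrees(struc.dihedral(pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3]))
    assert np.allclose(wrap_degrees(ours - ref), 0.0, atol=1e-4)  # f32 oracle


def test_phi_psi_roundtrip_through_builder():
    rng = np.random.default_rng(3)
    phi = rng.uniform(-179, 179, size=(4, 10))
    psi = rng.uniform(-179, 179, size=(4, 10))
    traj = trajectory_from_dihedrals(phi, psi)
    s = compute_phi_psi(traj, "A")
    assert np.allclose(wrap_degrees(s.phi[:, 1:] - phi[:, 1:]), 0, atol=1e-6)
    assert np.allclose(wrap_degrees(s.psi[:, :-1] - psi[:, :-1]), 0, atol=1e-6)
    assert np.isnan(s.phi[:, 0]).all() and np.isnan(s.psi[:, -1]).all()


def test_rmsda_examples():
    proto = PB_MATRIX[0]
    assert rmsda(proto, proto) == 0.0
    assert rmsda(proto + 360.0, proto) == pytest.approx(0.0, abs=1e-9)
    bumped = proto.copy()
    bumped[3] += 10.0
    assert rmsda(bumped, proto) == pytest.approx(np.sqrt(100 / 8), abs=1e-9)
    nan_win = proto.copy().astype(float)
    nan_win[0] = np.nan
    assert np.isnan(rmsda(nan_win, proto))


@given(st.integers(0, 15), st.floats(-720, 720, allow_nan=False))
def test_rmsda_periodicity(k, shift):
    shift = round(shift / 360) * 360.0
    assert rmsda(PB_MATRIX[k] + shift, PB_MATRIX[k]) == pytest.approx(0, abs=1e-6)


def test_ideal_helix_assigns_m():
    traj = trajectory_from_dihedrals(np.full((1, 12), -57.0),
                                     np.full((1, 12), -47.0))
    s = assign_pbs(compute_phi_psi(traj, "A")).strings()[0]
    assert s == "ZZ" + "m" * 8 + "ZZ"


def test_ideal_strand_assigns_d():
    traj = trajectory_from_dihedrals(np.full((1, 12), -120.0),
                                     np.full((1, 12), 130.0))
    s = assign_pbs(compute_phi_psi(traj, "A")).strings()[0]
    assert s == "ZZ" + "d" * 8 + "ZZ"


def test_five_residue_peptide_one_assignable():
    traj = trajectory_from_dihedrals(np.full((1, 5), -57.0),
                                     np.full((1, 5), -47.0))
    s = assign_pbs(compute_phi_psi(traj, "A")).strings()[0]
    assert len(s) == 5
    assert s[:2] == "ZZ" and s[3:] == "ZZ"
    assert s[2] in PB_LABELS


def test_z_count_at_least_four_per_chain(helix_tails):
    traj, _ = helix_tails
    labels = assign_pbs(compute_phi_psi(traj, "A")).labels
    z_per_frame = (labels == "Z").sum(axis=1)
    assert (z_per_frame == 4).all()  # all backbone atoms present


def test_assignment_rigid_motion_invariant(helix_tails):
    traj, _ = helix_tails
    sub = traj.with_frames(slice(0, 5))
    s1 = assign_pbs(compute_phi_psi(sub, "A")).strings()
    # arbitrary proper rotation + translation
    from scipy.spatial.transform import Rotation
    R = Rotation.from_euler("xyz", [31, -77, 123], degrees=True).as_matrix()
    moved = Trajectory(sub.residues, sub.coords @ R.T + np.array([5., -3., 9.]),
                       sub.times_ps, sub.label)
    s2 = assign_pbs(compute_phi_psi(moved, "A")).strings()
    assert s1 == s2


def test_assignment_equals_bruteforce_argmin():
    """Vectorised assignment must agree with an explicit 16-way RMSDA loop."""
    rng = np.random.default_rng(4)
    windows = rng.uniform(-180, 180, size=(1000, 8))

    def brute(win):
        best, best_d = None, np.inf
        for k, lbl in enumerate(PB_LABELS):  # lexical order breaks ties
            d = rmsda(win, PB_MATRIX[k])
            if d < best_d:
                best, best_d = lbl, d
        return best

    expected = [brute(w) for w in windows]

    # feed the same windows through assign_pbs via a synthetic DihedralSeries
    from pbtraj.pb import DihedralSeries

    F = windows.shape[0]
    phi = np.full((F, 5), np.nan)
    psi = np.full((F, 5), np.nan)
    psi[:, 0] = windows[:, 0]
    phi[:, 1] = windows[:, 1]
    psi[:, 1] = windows[:, 2]
    phi[:, 2] = windows[:, 3]
    psi[:, 2] = windows[:, 4]
    phi[:, 3] = windows[:, 5]
    psi[:, 3] = windows[:, 6]
    phi[:, 4] = windows[:, 7]
    series = DihedralSeries("A", np.arange(1, 6), phi, psi)
    got = assign_pbs(series).labels[:, 2]
    assert list(got) == expected


def test_windows_layout(probe_system):
    traj, _, _ = probe_system
    series = compute_phi_psi(traj.with_frames(slice(0, 3)), "A")
    win = dihedral_windows(series)
    assert np.isnan(win[:, :2]).all() and np.isnan(win[:, -2:]).all()
    i = 5
    assert np.allclose(win[:, i, 3], series.phi[:, i], equal_nan=True)
    assert np.allclose(win[:, i, 0], series.psi[:, i - 2], equal_nan=True)
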