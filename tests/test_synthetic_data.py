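"""Ground-truth generator: backbone builder, mixture sampling, ions, dimers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbtraj import (
    IonEvent,
    add_ions,
    assign_pbs,
    build_backbone,
    compute_phi_psi,
    make_dimer,
    make_helix_with_tails,
    sample_system,
    select_calpha,
    trajectory_from_dihedrals,
    write_multimodel_pdb,
)
from pbtraj.pb import wrap_degrees
from pbtraj.synth import GeometryParams, GroundTruth

from conftest import standard_probe_mixtures


@given(st.lists(st.tuples(st.floats(-179, 179), st.floats(-179, 179)),
                min_size=4, max_size=12))
@settings(max_examples=25)
def test_backbone_dihedral_roundtrip(angles):
    phi = np.array([[a for a, _ in angles]])
    psi = np.array([[b for _, b in angles]])
    traj = trajectory_from_dihedrals(phi, psi)
    s = compute_phi_psi(traj, "A")
    assert np.nanmax(np.abs(wrap_degrees(s.phi[:, 1:] - phi[:, 1:]))) < 1e-6
    assert np.nanmax(np.abs(wrap_degrees(s.psi[:, :-1] - psi[:, :-1]))) < 1e-6


def test_trans_peptide_ca_ca_spacing():
    traj = trajectory_from_dihedrals(np.full((1, 10), -57.0),
                                     np.full((1, 10), -47.0))
    ca = traj.coords[0][select_calpha(traj)]
    d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    assert np.allclose(d, 3.8, atol=0.05)


def test_backbone_rejects_midchain_nan():
    phi = np.full((1, 5), -57.0)
    phi[0, 2] = np.nan
    with pytest.raises(ValueError, match="mid-chain"):
        build_backbone(phi, np.full((1, 5), -47.0))


def test_geometry_params_validation():
    with pytest.raises(ValueError):
        GeometryParams(n_ca=-1.0)
    with pytest.raises(ValueError):
        GeometryParams(ang_n_ca_c=200.0)


def test_sample_system_validation():
    uniform = np.full(16, 1 / 16)
    with pytest.raises(ValueError, match="end"):
        sample_system(10, {352: uniform}, n_frames=5)
    with pytest.raises(ValueError, match="closer"):
        sample_system(20, {356: uniform, 358: uniform}, n_frames=5)
    with pytest.raises(ValueError, match="probability"):
        sample_system(20, {358: np.ones(16)}, n_frames=5)
    with pytest.raises(ValueError, match="jitter"):
        sample_system(20, {358: uniform}, n_frames=5, jitter_deg=20.0)


def test_probe_assignment_recovers_sampled_labels_exactly(probe_system):
    """Full-window stamping makes re-assignment reproduce every draw."""
    traj, gt, _ = probe_system
    seqs = assign_pbs(compute_phi_psi(traj, "A"))
    pos_index = {p: i for i, p in enumerate(seqs.author_numbers)}
    for probe, sampled in gt.sampled_labels.items():
        got = "".join(seqs.labels[:, pos_index[probe]])
        assert got == sampled


def test_generator_determinism_byte_identical(tmp_path):
    mixtures = standard_probe_mixtures()
    a1, _ = sample_system(25, mixtures, n_frames=20, seed=42)
    a2, _ = sample_system(25, mixtures, n_frames=20, seed=42)
    b, _ = sample_system(25, mixtures, n_frames=20, seed=43)
    p1, p2, p3 = (tmp_path / n for n in ("a1.pdb", "a2.pdb", "b.pdb"))
    write_multimodel_pdb(a1, p1)
    write_multimodel_pdb(a2, p2)
    write_multimodel_pdb(b, p3)
    assert p1.read_bytes() == p2.read_bytes()
    assert p1.read_bytes() != p3.read_bytes()


def test_helix_with_tails_ground_truth_partition():
    traj, gt = make_helix_with_tails(core_len=10, tail_len=3, n_frames=5,
                                     seed=0, start_number=352)
    assert gt.rigid_positions == list(range(355, 365))
    assert set(gt.flexible_positions) == {352, 353, 354, 365, 366, 367}
    nums = {r.author_number for r in traj.polymer_residues("A")}
    assert nums == set(gt.rigid_positions) | set(gt.flexible_positions)


def test_zero_tail_system_is_uniformly_rigid():
    from pbtraj import rmsf

    traj, gt = make_helix_with_tails(core_len=20, tail_len=0, n_frames=100,
                                     seed=1)
    assert gt.flexible_positions == []
    sel = select_calpha(traj)
    vals = rmsf(traj, sel)
    assert vals.max() < 1.0  # jitter-only fluctuation, no disordered region


def test_unbound_ion_stays_far():
    traj, _ = make_helix_with_tails(n_frames=30, seed=2)
    with_ion = add_ions(traj, [IonEvent(360, bind_frame=None)], seed=3)
    prot = np.flatnonzero(with_ion.atom_is_polymer)
    ion = np.flatnonzero(~with_ion.atom_is_polymer)
    d = np.linalg.norm(with_ion.coords[:, prot] - with_ion.coords[:, ion],
                       axis=2)
    assert d.min() >= 15.0


def test_scheduled_occupancy_helper():
    gt = GroundTruth(seed=0, ion_schedule=[
        IonEvent(360, bind_frame=0),
        IonEvent(365, bind_frame=10, unbind_frame=20),
        IonEvent(370, bind_frame=None),
    ])
    occ = gt.scheduled_occupancy(40)
    assert occ == {360: 1.0, 365: 0.25}


def test_ground_truth_json_roundtrip(tmp_path):
    mixtures = standard_probe_mixtures()
    _, gt = sample_system(25, mixtures, n_frames=10, seed=5)
    path = tmp_path / "gt.json"
    gt.to_json(path)
    back = GroundTruth.from_json(path)
    assert back.pb_mixtures.keys() == gt.pb_mixtures.keys()
    assert back.sampled_labels == gt.sampled_labels
    assert back.seed == gt.seed


def test_dimer_keeps_ions_and_duplicates_chain():
    traj, _ = make_helix_with_tails(n_frames=10, seed=6)
    with_ion = add_ions(traj, [IonEvent(360, bind_frame=0)], seed=7)
    dim, gt = make_dimer(with_ion, mode="stable", initial_offset_A=30.0)
    assert dim.polymer_chain_ids() == ["A", "B"]
    assert sum(r.hetero for r in dim.residues) == 1
    assert gt.dimer_mode["mode"] == "stable"
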