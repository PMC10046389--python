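"""Trajectory model, PDB round trip, atom selection, equilibration discard."""

import numpy as np
import pytest

from pbtraj import (
    IonEvent,
    add_ions,
    discard_equilibration,
    make_helix_with_tails,
    read_frame_table,
    read_multimodel_pdb,
    select_atoms,
    select_calpha,
    trajectory_from_dihedrals,
    write_frame_table,
    write_multimodel_pdb,
)
from pbtraj.trajectory import AtomRecord, ResidueRecord, Trajectory

PEPTIDE_PDB = """\
MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       3.300   1.600   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       4.200   2.700   0.100  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1       0.100   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.558   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.100   1.400   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       3.400   1.600   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       4.300   2.700   0.100  1.00  0.00           C
ENDMDL
"""


def _peptide_pdb_5res():
    phi = np.full((2, 5), -57.0)
    psi = np.full((2, 5), -47.0)
    return trajectory_from_dihedrals(phi, psi, start_number=1, with_cb=False)


def test_multimodel_parse_counts(tmp_path):
    p = tmp_path / "pep.pdb"
    p.write_text(PEPTIDE_PDB)
    traj = read_multimodel_pdb(p)
    assert traj.n_frames == 2
    assert len([r for r in traj.residues if r.is_polymer]) == 2
    assert traj.n_atoms == 5


def test_single_model_yields_one_frame(tmp_path):
    single = PEPTIDE_PDB.split("ENDMDL")[0].replace("MODEL        1\n", "")
    p = tmp_path / "one.pdb"
    p.write_text(single)
    assert read_multimodel_pdb(p).n_frames == 1


def test_thirteen_calcium_ions_roundtrip(tmp_path):
    traj, _ = make_helix_with_tails(n_frames=3, seed=0)
    chain_numbers = [r.author_number for r in traj.polymer_residues("A")]
    schedule = [IonEvent(chain_numbers[2 + 2 * k], bind_frame=0)
                for k in range(13)]
    with_ions = add_ions(traj, schedule, element="Ca", seed=1)
    p = tmp_path / "ions.pdb"
    write_multimodel_pdb(with_ions, p)
    back = read_multimodel_pdb(p)
    ion_res = [r for r in back.residues if r.hetero]
    assert len(ion_res) == 13
    assert all(r.atoms[0].element == "Ca" for r in ion_res)
    ca_ions = select_atoms(back, element="Ca")
    calphas = select_calpha(back)
    assert len(ca_ions) == 13
    assert not set(ca_ions) & set(calphas)


def test_inconsistent_model_reports_index(tmp_path):
    broken = PEPTIDE_PDB.replace(
        "ATOM      5  CA  GLY A   2       4.300   2.700   0.100  1.00  0.00           C\n",
        "")
    p = tmp_path / "bad.pdb"
    p.write_text(broken)
    with pytest.raises(ValueError, match="MODEL 2"):
        read_multimodel_pdb(p)


def test_pdb_roundtrip_precision(tmp_path):
    traj = _peptide_pdb_5res()
    p = tmp_path / "rt.pdb"
    write_multimodel_pdb(traj, p)
    back = read_multimodel_pdb(p)
    assert back.n_atoms == traj.n_atoms
    assert np.array_equal(back.atom_resnum, traj.atom_resnum)
    assert np.allclose(back.coords, traj.coords, atol=5e-4)  # PDB 3 decimals
    assert np.array_equal(back.times_ps, traj.times_ps)


def test_select_atoms_is_topology_only():
    traj = _peptide_pdb_5res()
    sel1 = select_calpha(traj)
    shifted = Trajectory(traj.residues, traj.coords + 100.0, traj.times_ps)
    assert np.array_equal(sel1, select_calpha(shifted))
    assert len(sel1) == 5


def test_select_absent_chain_is_empty():
    traj = _peptide_pdb_5res()
    assert select_atoms(traj, chain="Z").size == 0


def test_discard_equilibration_counts():
    phi = np.full((101, 5), -57.0)
    psi = np.full((101, 5), -47.0)
    traj = trajectory_from_dihedrals(phi, psi, stride_ps=100.0)
    cut = discard_equilibration(traj, 5000.0)
    assert cut.n_frames == 51
    assert cut.times_ps[0] == 5000.0 and cut.times_ps[-1] == 10000.0
    same = discard_equilibration(traj, 0.0)
    assert same.n_frames == traj.n_frames
    with pytest.raises(ValueError):
        discard_equilibration(traj, 10100.0)


def test_invariant_validation():
    res = [ResidueRecord("A", 1, "GLY", [AtomRecord("CA", "C")])]
    coords = np.zeros((2, 1, 3))
    with pytest.raises(ValueError, match="strictly increasing"):
        Trajectory(res, coords, np.array([5.0, 5.0]))
    with pytest.raises(ValueError, match="finite"):
        Trajectory(res, np.full((1, 1, 3), np.nan), np.array([0.0]))
    with pytest.raises(ValueError, match="atoms"):
        Trajectory(res, np.zeros((1, 2, 3)), np.array([0.0]))


def test_frame_table_roundtrip(tmp_path):
    traj = _peptide_pdb_5res()
    p = tmp_path / "frames.txt"
    write_frame_table(traj, p)
    back = read_frame_table(p, traj)
    assert np.allclose(back.coords, traj.coords, atol=1e-6)
    assert np.allclose(back.times_ps, traj.times_ps)
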