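"""Conformational-ensemble data model and I/O.

A :class:`Trajectory` couples a fixed topology (chains of residues of atoms,
with author residue numbering preserved, e.g. the 352-based numbering of the
calreticulin C-domain) with an ordered stack of coordinate frames in Angstrom
and times in picoseconds.  Multi-model PDB is the interchange format; a plain
whitespace-separated frame table (time + flattened coordinates) is supported
as a second dialect for synthetic ensembles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

log = logging.getLogger(__name__)

#: 3-letter codes treated as polymer (protein) residues.
STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

_TIME_REMARK = "REMARK 100 PBTRAJ TIME_PS"
_LABEL_REMARK = "REMARK 100 PBTRAJ LABEL"

#: default save stride when a PDB carries no time annotation (ps)
DEFAULT_STRIDE_PS = 100.0


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology; coordinates live in the frame stack."""

    name: str
    element: str

    def __post_init__(self):
        if not self.element:
            raise ValueError(f"atom {self.name!r}: element must be non-empty")


@dataclass
class ResidueRecord:
    chain_id: str
    author_number: int
    name: str
    atoms: list[AtomRecord]
    hetero: bool = False

    @property
    def is_polymer(self) -> bool:
        return (not self.hetero) and self.name in STANDARD_AA

    def atom_index(self, atom_name: str) -> int | None:
        """Index of *atom_name* within this residue, or None."""
        for i, a in enumerate(self.atoms):
            if a.name == atom_name:
                return i
        return None


@dataclass(frozen=True)
class Frame:
    """A read-only view of one snapshot."""

    index: int
    time_ps: float
    coords: np.ndarray  # (n_atoms, 3), Angstrom


class Trajectory:
    """Topology plus ordered coordinate frames.

    Parameters
    ----------
    residues:
        Topology as an ordered list of :class:`ResidueRecord` (chains are
        contiguous runs of equal ``chain_id``).
    coords:
        Array of shape ``(n_frames, n_atoms, 3)`` in Angstrom, atoms in
        topology order.
    times_ps:
        Strictly increasing frame times in picoseconds.
    label:
        Free-form system label (e.g. ``"CALRwt_Ca"``).
    """

    def __init__(self, residues: list[ResidueRecord], coords: np.ndarray,
                 times_ps: np.ndarray, label: str = ""):
        coords = np.asarray(coords, dtype=float)
        times_ps = np.asarray(times_ps, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if coords.shape[0] < 1:
            raise ValueError("a trajectory needs at least one frame")
        if times_ps.shape != (coords.shape[0],):
            raise ValueError("times_ps length must equal the frame count")
        if np.any(np.diff(times_ps) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        n_atoms = sum(len(r.atoms) for r in residues)
        if n_atoms != coords.shape[1]:
            raise ValueError(
                f"topology has {n_atoms} atoms but frames have {coords.shape[1]}")
        for res in residues:
            seen = set()
            for a in res.atoms:
                if a.name in seen:
                    raise ValueError(
                        f"duplicate atom {a.name!r} in residue "
                        f"{res.chain_id}/{res.author_number}")
                seen.add(a.name)
        self._check_numbering(residues)
        self.residues = residues
        self.coords = coords
        self.times_ps = times_ps
        self.label = label
        self._build_atom_arrays()

    @staticmethod
    def _check_numbering(residues: list[ResidueRecord]) -> None:
        prev: dict[str, int] = {}
        for r in residues:
            if r.is_polymer:
                if r.chain_id in prev and r.author_number <= prev[r.chain_id]:
                    raise ValueError(
                        f"author numbering not strictly increasing in chain "
                        f"{r.chain_id!r} at residue {r.author_number}")
                prev[r.chain_id] = r.author_number

    def _build_atom_arrays(self) -> None:
        chain, resnum, resname, aname, elem, poly, resord = [], [], [], [], [], [], []
        for i, r in enumerate(self.residues):
            for a in r.atoms:
                chain.append(r.chain_id)
                resnum.append(r.author_number)
                resname.append(r.name)
                aname.append(a.name)
                elem.append(a.element)
                poly.append(r.is_polymer)
                resord.append(i)
        self.atom_chain = np.array(chain, dtype=object)
        self.atom_resnum = np.array(resnum, dtype=int)
        self.atom_resname = np.array(resname, dtype=object)
        self.atom_name = np.array(aname, dtype=object)
        self.atom_element = np.array([e.capitalize() for e in elem], dtype=object)
        self.atom_is_polymer = np.array(poly, dtype=bool)
        self.atom_residue_index = np.array(resord, dtype=int)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for r in self.residues:
            if r.chain_id not in out:
                out.append(r.chain_id)
        return out

    def polymer_chain_ids(self) -> list[str]:
        out: list[str] = []
        for r in self.residues:
            if r.is_polymer and r.chain_id not in out:
                out.append(r.chain_id)
        return out

    def frame(self, i: int) -> Frame:
        return Frame(index=i, time_ps=float(self.times_ps[i]), coords=self.coords[i])

    def polymer_residues(self, chain: str) -> list[ResidueRecord]:
        return [r for r in self.residues if r.is_polymer and r.chain_id == chain]

    def with_frames(self, mask_or_idx) -> "Trajectory":
        return Trajectory(self.residues, self.coords[mask_or_idx],
                          self.times_ps[mask_or_idx], self.label)


def select_atoms(traj: Trajectory, chain: str | None = None,
                 atom_name: str | None = None,
                 element: str | None = None) -> np.ndarray:
    """Stable topology-order atom indices matching the selection.

    ``atom_name`` filtering is restricted to polymer residues: atom names are
    only meaningful within the polypeptide, so selecting ``"CA"`` yields the
    C-alpha set and never a calcium ion (ions are addressed via ``element``,
    which matches any residue).  An empty selection returns an empty array.
    """
    mask = np.ones(traj.n_atoms, dtype=bool)
    if chain is not None:
        mask &= traj.atom_chain == chain
    if atom_name is not None:
        mask &= (traj.atom_name == atom_name) & traj.atom_is_polymer
    if element is not None:
        mask &= traj.atom_element == element.capitalize()
    return np.flatnonzero(mask)


def select_calpha(traj: Trajectory, chain: str | None = None) -> np.ndarray:
    """C-alpha atoms of polymer residues (the paper's RMSD/RMSF atom set)."""
    return select_atoms(traj, chain=chain, atom_name="CA")


def discard_equilibration(traj: Trajectory, t_cut_ps: float) -> Trajectory:
    """Drop frames with ``time_ps < t_cut_ps`` (default protocol: 5000 ps).

    Raises if nothing would remain.
    """
    if t_cut_ps < 0:
        raise ValueError("t_cut_ps must be >= 0")
    keep = traj.times_ps >= t_cut_ps
    if not keep.any():
        raise ValueError(
            f"equilibration cut {t_cut_ps} ps removes all {traj.n_frames} frames")
    return traj.with_frames(keep)


# -- PDB I/O ---------------------------------------------------------------

def _element_from_name(atom_name: str, res_name: str) -> str:
    """Fallback element inference when PDB columns 77-78 are blank."""
    if res_name.strip() in {"CA", "NA", "CL", "MG", "K", "ZN"}:
        return res_name.strip().capitalize()
    stripped = "".join(c for c in atom_name if c.isalpha())
    return stripped[:1].capitalize() if stripped else "X"


def _scan_model_atom_counts(lines: list[str]) -> list[int]:
    counts: list[int] = []
    current = 0
    in_model = False
    for ln in lines:
        rec = ln[:6]
        if rec.startswith("MODEL"):
            in_model = True
            current = 0
        elif rec.startswith("ENDMDL"):
            counts.append(current)
            in_model = False
        elif rec.startswith(("ATOM  ", "HETATM")):
            current += 1
    if not counts:  # no MODEL records: single implicit model
        counts = [current] if current else []
    elif in_model:
        counts.append(current)
    return counts


def read_multimodel_pdb(path, times_ps=None, stride_ps: float = DEFAULT_STRIDE_PS,
                        label: str | None = None) -> Trajectory:
    """Read a (multi-model) PDB file into a :class:`Trajectory`.

    One frame per MODEL block; a single-model file yields a one-frame
    trajectory.  HETATM ion records are retained as single-atom hetero
    residues with the element parsed from columns 77-78 (falling back to the
    atom/residue name).  Frame times are taken from ``times_ps`` if given,
    else from a ``REMARK 100 PBTRAJ TIME_PS`` header written by
    :func:`write_multimodel_pdb`, else synthesised as ``index * stride_ps``.

    Raises
    ------
    ValueError
        If MODEL blocks disagree in atom count (the offending model is named)
        or coordinates are missing/malformed.
    """
    pdb = PDBFile.read(str(path))
    counts = _scan_model_atom_counts(pdb.lines)
    if len(set(counts)) > 1:
        bad = next(i for i, c in enumerate(counts, start=1) if c != counts[0])
        raise ValueError(
            f"inconsistent atom count across models: MODEL {bad} has "
            f"{counts[bad - 1]} atoms, MODEL 1 has {counts[0]}")
    if not counts or counts[0] == 0:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    try:
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite parse failure -> missing/garbled coords
        raise ValueError(f"{path}: failed to parse coordinates: {exc}") from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])

    residues: list[ResidueRecord] = []
    key = None
    for i in range(stack.array_length()):
        k = (stack.chain_id[i], int(stack.res_id[i]), stack.res_name[i])
        elem = str(stack.element[i]).strip()
        if not elem:
            elem = _element_from_name(str(stack.atom_name[i]), str(stack.res_name[i]))
        atom = AtomRecord(name=str(stack.atom_name[i]), element=elem.capitalize())
        if k != key:
            residues.append(ResidueRecord(
                chain_id=str(stack.chain_id[i]), author_number=int(stack.res_id[i]),
                name=str(stack.res_name[i]), atoms=[atom],
                hetero=bool(stack.hetero[i])))
            key = k
        else:
            residues[-1].atoms.append(atom)

    n_frames = stack.stack_depth()
    if times_ps is None:
        times_ps = _parse_time_remark(pdb.lines, n_frames)
    if times_ps is None:
        times_ps = np.arange(n_frames, dtype=float) * stride_ps
    if label is None:
        label = _parse_label_remark(pdb.lines) or ""
    return Trajectory(residues, stack.coord, np.asarray(times_ps, float), label)


def _parse_time_remark(lines, n_frames):
    vals = []
    for ln in lines:
        if ln.startswith(_TIME_REMARK):
            vals.extend(float(tok) for tok in ln[len(_TIME_REMARK):].split())
    if len(vals) == n_frames:
        return np.array(vals)
    if vals:
        log.warning("time remark has %d values for %d frames; ignoring",
                    len(vals), n_frames)
    return None


def _parse_label_remark(lines):
    for ln in lines:
        if ln.startswith(_LABEL_REMARK):
            return ln[len(_LABEL_REMARK):].strip()
    return None


def write_multimodel_pdb(traj: Trajectory, path) -> None:
    """Write a trajectory as a multi-model PDB with time/label remarks."""
    n = traj.n_atoms
    arr = struc.AtomArray(n)
    arr.chain_id = traj.atom_chain.astype("U4")
    arr.res_id = traj.atom_resnum
    arr.res_name = traj.atom_resname.astype("U5")
    arr.atom_name = traj.atom_name.astype("U6")
    arr.element = np.array([e.upper() for e in traj.atom_element], dtype="U2")
    arr.hetero = ~traj.atom_is_polymer
    stack = struc.from_template(arr, traj.coords)
    pdb = PDBFile()
    pdb.set_structure(stack)
    remarks = []
    if traj.label:
        remarks.append(f"{_LABEL_REMARK} {traj.label}")
    times = " ".join(f"{t:g}" for t in traj.times_ps)
    # keep remark lines comfortably short
    toks = times.split()
    for i in range(0, len(toks), 12):
        remarks.append(f"{_TIME_REMARK} {' '.join(toks[i:i + 12])}")
    pdb.lines = remarks + pdb.lines
    pdb.write(str(path))


# -- whitespace frame-table dialect ---------------------------------------

def write_frame_table(traj: Trajectory, path) -> None:
    """Frame table: one row per frame, ``time_ps x1 y1 z1 x2 y2 z2 ...``."""
    flat = traj.coords.reshape(traj.n_frames, -1)
    data = np.column_stack([traj.times_ps, flat])
    np.savetxt(str(path), data, fmt="%.6f",
               header=f"pbtraj frame table  atoms={traj.n_atoms}  label={traj.label}")


def read_frame_table(path, template: Trajectory) -> Trajectory:
    """Read a frame table, taking the topology from *template*."""
    data = np.loadtxt(str(path), ndmin=2)
    times = data[:, 0]
    coords = data[:, 1:].reshape(data.shape[0], -1, 3)
    if coords.shape[1] != template.n_atoms:
        raise ValueError(
            f"frame table has {coords.shape[1]} atoms, template has "
            f"{template.n_atoms}")
    return Trajectory(template.residues, coords, times, template.label)
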