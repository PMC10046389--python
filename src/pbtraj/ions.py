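"""Ion-binding analysis: per-residue occupancy, binding onset, bound counts.

A residue is "occupied" in a frame when any ion of the requested element lies
within the distance cutoff (default 3 A) of any of the residue's heavy
atoms (hydrogens excluded; coarse models often lack them).  No periodic
minimum-image correction is applied: input ensembles are assumed unwrapped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory import Trajectory, select_atoms

DEFAULT_CUTOFF_A = 3.0
#: default persistence for binding onset: 10 frames = 1 ns at a 100 ps stride
DEFAULT_PERSISTENCE_FRAMES = 10


@dataclass
class OccupancyProfile:
    chain_ids: np.ndarray       # (R,) per polymer residue
    author_numbers: np.ndarray  # (R,)
    occupancy: np.ndarray       # (R,) fraction of frames in [0, 1]
    ion_element: str
    cutoff_A: float
    n_frames: int


@dataclass
class BindingOnset:
    """Per ion: first time at which it is persistently bound (NaN = never)."""

    ion_labels: list[str]
    onset_time_ps: np.ndarray   # (I,), NaN where never bound
    persistence_frames: int


def _ion_indices(traj: Trajectory, ion_element: str) -> np.ndarray:
    idx = select_atoms(traj, element=ion_element)
    idx = idx[~traj.atom_is_polymer[idx]]
    if idx.size == 0:
        raise ValueError(f"no {ion_element!r} ions present in the system")
    return idx


def _protein_heavy(traj: Trajectory) -> np.ndarray:
    mask = traj.atom_is_polymer & (traj.atom_element != "H")
    return np.flatnonzero(mask)


def _min_dist_frame(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(P, I) pairwise distances for one frame."""
    return np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)


def ion_occupancy(traj: Trajectory, ion_element: str,
                  cutoff_A: float = DEFAULT_CUTOFF_A) -> OccupancyProfile:
    """Fraction of frames with an ion within *cutoff_A* of each residue.

    Occupancy is binary per frame (presence, not ion count) and is monotone
    non-decreasing in the cutoff.
    """
    ions = _ion_indices(traj, ion_element)
    prot = _protein_heavy(traj)
    res_idx = traj.atom_residue_index[prot]
    uniq, seg_start = np.unique(res_idx, return_index=True)
    hits = np.zeros(len(uniq), dtype=int)
    for f in range(traj.n_frames):
        d = _min_dist_frame(traj.coords[f][prot], traj.coords[f][ions])
        per_atom = d.min(axis=1)
        per_res = np.minimum.reduceat(per_atom, seg_start)
        hits += per_res <= cutoff_A
    chains = np.array([traj.residues[i].chain_id for i in uniq], dtype=object)
    numbers = np.array([traj.residues[i].author_number for i in uniq])
    return OccupancyProfile(chain_ids=chains, author_numbers=numbers,
                            occupancy=hits / traj.n_frames,
                            ion_element=ion_element, cutoff_A=cutoff_A,
                            n_frames=traj.n_frames)


def _bound_matrix(traj: Trajectory, ion_element: str, cutoff_A: float):
    """(F, I) bool: ion within cutoff of any protein heavy atom."""
    ions = _ion_indices(traj, ion_element)
    prot = _protein_heavy(traj)
    F = traj.n_frames
    bound = np.zeros((F, ions.size), dtype=bool)
    for f in range(F):
        d = _min_dist_frame(traj.coords[f][prot], traj.coords[f][ions])
        bound[f] = d.min(axis=0) <= cutoff_A
    return bound, ions


def binding_onset(traj: Trajectory, ion_element: str,
                  cutoff_A: float = DEFAULT_CUTOFF_A,
                  persistence_frames: int = DEFAULT_PERSISTENCE_FRAMES) -> BindingOnset:
    """Earliest time from which each ion stays bound for >= *persistence_frames*
    consecutive frames (NaN if that never happens).

    With ``persistence_frames=1`` a single-frame grazing contact counts as an
    onset, which is why the default asks for sustained contact.
    """
    if persistence_frames < 1:
        raise ValueError("persistence_frames must be >= 1")
    bound, ions = _bound_matrix(traj, ion_element, cutoff_A)
    F, n_ions = bound.shape
    onset = np.full(n_ions, np.nan)
    for j in range(n_ions):
        run = 0
        for f in range(F):
            run = run + 1 if bound[f, j] else 0
            if run >= persistence_frames:
                onset[j] = traj.times_ps[f - persistence_frames + 1]
                break
    labels = [f"{ion_element}_{k + 1}" for k in range(n_ions)]
    return BindingOnset(ion_labels=labels, onset_time_ps=onset,
                        persistence_frames=persistence_frames)


def bound_count_series(traj: Trajectory, ion_element: str,
                       cutoff_A: float = DEFAULT_CUTOFF_A) -> np.ndarray:
    """Per-frame count of ions within cutoff of the protein."""
    bound, _ = _bound_matrix(traj, ion_element, cutoff_A)
    return bound.sum(axis=1)
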