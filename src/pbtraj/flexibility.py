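"""C-alpha RMSD time series and per-residue RMSF.

Frames are rigid-body superposed (least-squares, proper rotation) before any
deviation is measured, so both statistics are invariant under global
rotation/translation of the ensemble.  The RMSD reference is the first
retained frame (the "starting structure"); the RMSF deviation reference is
each atom's time-average position after superposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .trajectory import Trajectory, select_calpha


@dataclass
class FlexibilityProfile:
    times_ps: np.ndarray
    rmsd: np.ndarray            # (F,) Angstrom vs reference frame
    author_numbers: np.ndarray  # (R,)
    rmsf: np.ndarray            # (R,) Angstrom
    selection: str
    reference_frame: int


def superpose(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid fit (Kabsch) of *mobile* onto *reference*.

    Returns ``(R, t)`` with ``mobile @ R.T + t`` superposed; ``R`` is a
    proper rotation (det = +1).  Requires at least 3 non-degenerate points.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both be (N, 3)")
    if mobile.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - rc, mobile - mc)
    R = rot.as_matrix()
    t = rc - R @ mc
    return R, t


def _fit_frames(coords: np.ndarray, fit_idx: np.ndarray, ref_frame: int):
    """Superpose every frame onto *ref_frame* using the fit selection."""
    ref = coords[ref_frame][fit_idx]
    out = np.empty_like(coords)
    for i in range(coords.shape[0]):
        R, t = superpose(coords[i][fit_idx], ref)
        out[i] = coords[i] @ R.T + t
    return out


def rmsd_series(traj: Trajectory, selection: np.ndarray,
                reference: int = 0,
                fit_selection: np.ndarray | None = None) -> np.ndarray:
    """Per-frame C-alpha RMSD (A) against the reference frame.

    Each frame is first superposed onto the reference using
    ``fit_selection`` (defaults to ``selection``), then
    ``sqrt(mean |x - x_ref|^2)`` is taken over ``selection``.
    """
    selection = np.asarray(selection)
    if selection.size == 0:
        raise ValueError("empty selection")
    fit = selection if fit_selection is None else np.asarray(fit_selection)
    fitted = _fit_frames(traj.coords, fit, reference)
    d = fitted[:, selection] - fitted[reference][selection]
    return np.sqrt(np.mean(np.sum(d ** 2, axis=2), axis=1))


def rmsf(traj: Trajectory, selection: np.ndarray,
         reference: int = 0,
         fit_selection: np.ndarray | None = None) -> np.ndarray:
    """Per-atom RMSF (A): fluctuation about the time-average position.

    All frames are superposed onto the reference frame (single pass, no
    iterative mean refinement), the mean structure is computed post-fit, and
    per selected atom ``sqrt(mean_t |x_t - <x>|^2)`` is returned.
    """
    selection = np.asarray(selection)
    if selection.size == 0:
        raise ValueError("empty selection")
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    fit = selection if fit_selection is None else np.asarray(fit_selection)
    fitted = _fit_frames(traj.coords, fit, reference)[:, selection]
    mean = fitted.mean(axis=0)
    d = fitted - mean
    return np.sqrt(np.mean(np.sum(d ** 2, axis=2), axis=0))


def flexibility_profile(traj: Trajectory, chain: str | None = None,
                        reference: int = 0) -> FlexibilityProfile:
    """RMSD series + per-residue RMSF on the C-alpha set of *chain*."""
    sel = select_calpha(traj, chain)
    if sel.size == 0:
        raise ValueError(f"no C-alpha atoms in chain {chain!r}")
    numbers = traj.atom_resnum[sel]
    return FlexibilityProfile(
        times_ps=traj.times_ps,
        rmsd=rmsd_series(traj, sel, reference=reference),
        author_numbers=numbers,
        rmsf=rmsf(traj, sel, reference=reference),
        selection=f"CA chain={chain or 'all'}",
        reference_frame=reference,
    )
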