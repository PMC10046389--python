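"""Dimer geometry: inter-chain anchor distances and separation verdicts.

For two-chain systems the C-alpha/C-alpha distance between same-numbered
anchor residues is tracked per frame; a dimer is called "separated" when the
smallest anchor distance stays above a threshold for the terminal stretch of
the trajectory.  Threshold and persistence are reported configuration, not
fixed science: published separations reach ~100-250 A while stable dimers
oscillate near their initial contact distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory import Trajectory

DEFAULT_THRESHOLD_A = 50.0
DEFAULT_PERSISTENCE_FRACTION = 0.2

#: anchor residue triplets per CALR system, as used in the dimer analyses
DEFAULT_ANCHORS: dict[str, tuple[int, int, int]] = {
    "wt": (356, 371, 386),
    "A": (366, 385, 400),
    "B": (366, 400, 419),
    "D": (352, 370, 388),
    "E": (356, 371, 386),
}


@dataclass
class AnchorDistanceSeries:
    times_ps: np.ndarray
    anchors: np.ndarray          # (A,) author numbers
    distances: np.ndarray        # (F, A) Angstrom
    chain1: str
    chain2: str


@dataclass
class SeparationVerdict:
    label: str                   # "stable" | "separated"
    onset_time_ps: float | None  # defined iff separated
    max_distance_A: float
    threshold_A: float
    persistence_fraction: float


def _calpha_of(traj: Trajectory, chain: str, author_number: int) -> int:
    for i in np.flatnonzero((traj.atom_chain == chain)
                            & (traj.atom_resnum == author_number)
                            & (traj.atom_name == "CA")
                            & traj.atom_is_polymer):
        return int(i)
    raise ValueError(
        f"anchor residue {author_number} has no C-alpha on chain {chain!r}")


def anchor_distances(traj: Trajectory, chain1: str, chain2: str,
                     anchors) -> AnchorDistanceSeries:
    """Per-frame C-alpha distances between same-numbered residues of the
    two chains, one column per anchor."""
    anchors = np.asarray(list(anchors), dtype=int)
    i1 = [_calpha_of(traj, chain1, a) for a in anchors]
    i2 = [_calpha_of(traj, chain2, a) for a in anchors]
    d = np.linalg.norm(traj.coords[:, i1] - traj.coords[:, i2], axis=2)
    return AnchorDistanceSeries(times_ps=traj.times_ps, anchors=anchors,
                                distances=d, chain1=chain1, chain2=chain2)


def classify_separation(series: AnchorDistanceSeries,
                        threshold_A: float = DEFAULT_THRESHOLD_A,
                        persistence_fraction: float = DEFAULT_PERSISTENCE_FRACTION,
                        ) -> SeparationVerdict:
    """Separated iff the min-over-anchors distance exceeds *threshold_A*
    throughout the final *persistence_fraction* of frames; the onset is the
    first frame of that terminal excursion.  A transient spike that returns
    below threshold leaves the verdict "stable"."""
    if threshold_A <= 0:
        raise ValueError("threshold_A must be > 0")
    if not 0 < persistence_fraction <= 1:
        raise ValueError("persistence_fraction must be in (0, 1]")
    m = series.distances.min(axis=1)
    F = m.size
    k = max(1, int(np.ceil(persistence_fraction * F)))
    separated = bool(np.all(m[F - k:] > threshold_A))
    onset = None
    if separated:
        i = F - 1
        while i > 0 and m[i - 1] > threshold_A:
            i -= 1
        onset = float(series.times_ps[i])
    return SeparationVerdict(label="separated" if separated else "stable",
                             onset_time_ps=onset,
                             max_distance_A=float(series.distances.max()),
                             threshold_A=threshold_A,
                             persistence_fraction=persistence_fraction)


def disulfide_distance(traj: Trajectory, chain1: str, chain2: str,
                       res1: int, res2: int):
    """Per-frame S-gamma/S-gamma distance between two residues across chains.

    Falls back to C-alpha/C-alpha (flagged) when either S-gamma is absent.
    Returns ``(distances, used_sg)``.  A bonded cystine sits near 2.05 A;
    values of ~7 A or more indicate the bridge is not formed.
    """

    def _atom(chain, num, name):
        hits = np.flatnonzero((traj.atom_chain == chain)
                              & (traj.atom_resnum == num)
                              & (traj.atom_name == name)
                              & traj.atom_is_polymer)
        return int(hits[0]) if hits.size else None

    s1, s2 = _atom(chain1, res1, "SG"), _atom(chain2, res2, "SG")
    used_sg = s1 is not None and s2 is not None
    if not used_sg:
        s1, s2 = _atom(chain1, res1, "CA"), _atom(chain2, res2, "CA")
        if s1 is None or s2 is None:
            raise ValueError(
                f"residues {res1}/{chain1} and {res2}/{chain2} lack both SG "
                "and CA atoms")
    d = np.linalg.norm(traj.coords[:, s1] - traj.coords[:, s2], axis=1)
    return d, used_sg
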