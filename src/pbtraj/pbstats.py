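"""Per-position PB frequency profiles, N_eq, and profile comparison.

N_eq(i) = exp(-sum_x f_x(i) ln f_x(i)) is the equivalent number of Protein
Blocks sampled at position i: 1 means a single block is ever observed
(rigid), 16 the uniform/random limit.  Two systems are contrasted per
position by the absolute N_eq difference and by

    dPB(i) = sum_x |f_x^S1(i) - f_x^S2(i)|,

the L1 distance between the frequency vectors, 0 for identical profiles and
2 for disjoint support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pb import PB_LABELS, NOT_ASSIGNED, PBSequences

log = logging.getLogger(__name__)

#: report-annotation defaults (config keys, not hard-coded science):
#: N_eq above the first is flagged "disordered-like", at or below the second
#: "rigid", mirroring the field's reading of per-position N_eq plots.
DISORDER_NEQ_THRESHOLD = 6.0
RIGID_NEQ_THRESHOLD = 2.0

_LABEL_INDEX = {c: i for i, c in enumerate(PB_LABELS)}


@dataclass
class PBProfile:
    """Position x 16 PB frequencies accumulated over frames.

    ``counts[r, x]`` is the number of frames in which position ``r`` was
    assigned block ``x``; ``n_assignable[r]`` the number of frames where the
    position was assignable at all.  ``Z`` positions are excluded rather than
    counted as a 17th state, so assignable rows sum to one.
    """

    positions: np.ndarray      # (R,) author numbers
    counts: np.ndarray         # (R, 16)
    n_frames: int

    @property
    def n_assignable(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def frequencies(self) -> np.ndarray:
        """(R, 16) frequencies; NaN rows where a position is never assignable."""
        n = self.n_assignable.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.counts / n[:, None]
        f[n == 0] = np.nan
        return f

    @property
    def assignable(self) -> np.ndarray:
        return self.n_assignable > 0


@dataclass
class NeqProfile:
    positions: np.ndarray
    values: np.ndarray  # NaN where never assignable


@dataclass
class ProfileComparison:
    """Per aligned position: dN_eq in [0, 15] and dPB in [0, 2]."""

    positions: np.ndarray
    delta_neq: np.ndarray | None = None
    delta_pb: np.ndarray | None = None


def build_profile(pb: PBSequences | tuple) -> PBProfile:
    """Accumulate per-position PB counts over frames.

    Accepts a :class:`~pbtraj.pb.PBSequences` or a ``(positions, strings)``
    pair.  Positions never assignable are flagged (NaN frequencies) and are
    excluded from N_eq / dPB downstream.
    """
    if isinstance(pb, PBSequences):
        positions, labels = pb.author_numbers, pb.labels
    else:
        positions, strings = pb
        positions = np.asarray(positions)
        labels = np.array([list(s) for s in strings])
    F, R = labels.shape
    if R != len(positions):
        raise ValueError("string length must equal the number of positions")
    counts = np.zeros((R, 16), dtype=int)
    for x, k in _LABEL_INDEX.items():
        counts[:, k] = (labels == x).sum(axis=0)
    bad = ~np.isin(labels, list(PB_LABELS + NOT_ASSIGNED))
    if bad.any():
        raise ValueError(f"unknown PB symbol {labels[bad][0]!r}")
    prof = PBProfile(positions=positions, counts=counts, n_frames=F)
    never = ~prof.assignable
    if never.any():
        log.info("%d positions never assignable: %s", never.sum(),
                 positions[never].tolist())
    return prof


def neq_from_frequencies(f: np.ndarray) -> np.ndarray | float:
    """N_eq = exp(-sum f ln f) with 0 ln 0 = 0; operates on the last axis."""
    f = np.asarray(f, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(f > 0, f * np.log(f), 0.0)
    out = np.exp(-np.sum(terms, axis=-1))
    return float(out) if out.ndim == 0 else out


def neq(profile: PBProfile) -> NeqProfile:
    """Per-position equivalent number of PBs; NaN where never assignable."""
    f = profile.frequencies
    vals = np.where(profile.assignable, neq_from_frequencies(np.nan_to_num(f)),
                    np.nan)
    return NeqProfile(positions=profile.positions, values=vals)


def _align(pos1: np.ndarray, pos2: np.ndarray, pairing: dict | None):
    """Index pairs for aligned positions (author-number identity by default)."""
    if pairing is None:
        pairing = {int(p): int(p) for p in pos1}
    where2 = {int(p): j for j, p in enumerate(pos2)}
    i1, i2, pos = [], [], []
    unmatched = []
    for i, p in enumerate(pos1):
        q = pairing.get(int(p))
        if q is not None and q in where2:
            i1.append(i)
            i2.append(where2[q])
            pos.append(int(p))
        else:
            unmatched.append(int(p))
    if unmatched:
        log.warning("excluding %d unaligned positions: %s...",
                    len(unmatched), unmatched[:8])
    if not pos:
        raise ValueError("no aligned positions between the two systems")
    return np.array(i1), np.array(i2), np.array(pos)


def delta_neq(n1: NeqProfile, n2: NeqProfile,
              pairing: dict | None = None) -> ProfileComparison:
    """|N_eq1 - N_eq2| per aligned position (symmetric; range [0, 15])."""
    i1, i2, pos = _align(n1.positions, n2.positions, pairing)
    ok = ~(np.isnan(n1.values[i1]) | np.isnan(n2.values[i2]))
    if not ok.all():
        log.info("excluding %d never-assignable positions from delta_neq",
                 (~ok).sum())
    return ProfileComparison(positions=pos[ok],
                             delta_neq=np.abs(n1.values[i1][ok]
                                              - n2.values[i2][ok]))


def delta_pb(p1: PBProfile, p2: PBProfile,
             pairing: dict | None = None) -> ProfileComparison:
    """L1 distance between frequency vectors per aligned position ([0, 2])."""
    i1, i2, pos = _align(p1.positions, p2.positions, pairing)
    ok = p1.assignable[i1] & p2.assignable[i2]
    if not ok.all():
        log.info("excluding %d never-assignable positions from delta_pb",
                 (~ok).sum())
    f1, f2 = p1.frequencies[i1][ok], p2.frequencies[i2][ok]
    return ProfileComparison(positions=pos[ok],
                             delta_pb=np.sum(np.abs(f1 - f2), axis=1))


def export_pb_map(profile: PBProfile) -> pd.DataFrame:
    """Position x PB frequency map: rows = the 16 PBs a..p, columns =
    author-numbered positions.  Column sums are 1 at assignable positions;
    suitable for heat-map rendering."""
    return pd.DataFrame(profile.frequencies.T, index=list(PB_LABELS),
                        columns=profile.positions)


def annotate_neq(nprof: NeqProfile,
                 disorder_threshold: float = DISORDER_NEQ_THRESHOLD,
                 rigid_threshold: float = RIGID_NEQ_THRESHOLD) -> pd.DataFrame:
    """N_eq table with a qualitative flexibility flag per position."""
    flag = np.full(nprof.values.shape, "intermediate", dtype=object)
    flag[nprof.values > disorder_threshold] = "disordered-like"
    flag[nprof.values <= rigid_threshold] = "rigid"
    flag[np.isnan(nprof.values)] = "unassignable"
    return pd.DataFrame({"author_number": nprof.positions,
                         "neq": nprof.values, "flag": flag})
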