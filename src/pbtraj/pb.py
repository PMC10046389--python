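"""Backbone dihedrals and Protein Blocks (PB) assignment.

The Protein Blocks structural alphabet describes local backbone conformation
with 16 prototypes labelled ``a``..``p``.  Each prototype is an 8-vector of
dihedrals spanning five consecutive residues,

    (psi(i-2), phi(i-1), psi(i-1), phi(i), psi(i), phi(i+1), psi(i+1), phi(i+2)),

and a residue is assigned the label of the prototype closest to its own
window under RMSDA (root-mean-square deviation over angles with shortest-arc
wrapping).  PB ``m`` is the alpha-helix core prototype and PB ``d`` the
central beta-strand prototype; ``a``-``c`` are strand N-caps, ``e``/``f``
strand C-caps, ``k``/``l`` helix N-caps, ``n``-``p`` helix C-caps, and
``a``-``j`` cover coils.  Positions whose window is incomplete (the first
and last two residues of a chain, or any residue with missing backbone
atoms) carry the sentinel ``Z`` and are excluded from downstream frequency
statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .trajectory import Trajectory

log = logging.getLogger(__name__)

PB_LABELS = "abcdefghijklmnop"
NOT_ASSIGNED = "Z"

# Canonical 16-prototype dihedral table of the Protein Blocks alphabet
# (de Brevern, Etchebest & Hazout 2000), as distributed with the PBxplore
# assignment tool.  Row order follows the window layout in the module
# docstring; degrees.
PB_REFERENCE_ANGLES: dict[str, tuple[float, ...]] = {
    "a": ( 41.14,   75.53,  13.92,  -99.80, 131.88,  -96.27, 122.08,  -99.68),
    "b": (108.24,  -90.12, 119.54,  -92.21, -18.06, -128.93, 147.04,  -99.90),
    "c": (-11.61, -105.66,  94.81, -106.09, 133.56, -106.93, 135.97, -100.63),
    "d": (141.98, -112.79, 132.20, -114.79, 140.11, -111.05, 139.54, -103.16),
    "e": (133.25, -112.37, 137.64, -108.13, 133.00,  -87.30, 120.54,   77.40),
    "f": (116.40, -105.53, 129.32,  -96.68, 140.72,  -74.19, -26.65,  -94.51),
    "g": (  0.40,  -81.83,   4.91, -100.59,  85.50,  -71.65, 130.78,   84.98),
    "h": (119.14, -102.58, 130.83,  -67.91, 121.55,   76.25,  -2.95,  -90.88),
    "i": (130.68,  -56.92, 119.26,   77.85,  10.42,  -99.43, 141.40,  -98.01),
    "j": (114.32, -121.47, 118.14,   82.88, -150.05, -83.81,  23.35,  -85.82),
    "k": (117.16,  -95.41, 140.40,  -59.35, -29.23,  -72.39, -25.08,  -76.16),
    "l": (139.20,  -55.96, -32.70,  -68.51, -26.09,  -74.44, -22.60,  -71.74),
    "m": (-39.62,  -64.73, -39.52,  -65.54, -38.88,  -66.89, -37.76,  -70.19),
    "n": (-35.34,  -65.03, -38.12,  -66.34, -29.51,  -89.10,  -2.91,   77.90),
    "o": (-45.29,  -67.44, -27.72,  -87.27,   5.13,   77.49,  30.71,  -93.23),
    "p": (-27.09,  -86.14,   0.30,   59.85,  21.51,  -96.30, 132.67,  -92.91),
}

#: (16, 8) prototype matrix in label order.
PB_MATRIX = np.array([PB_REFERENCE_ANGLES[c] for c in PB_LABELS])


def wrap_degrees(x):
    """Map angle differences into (-180, 180] (shortest arc)."""
    w = np.mod(np.asarray(x, dtype=float) + 180.0, 360.0) - 180.0
    return np.where(w == -180.0, 180.0, w)


def dihedral(p0, p1, p2, p3):
    """Signed dihedral p0-p1-p2-p3 in degrees, IUPAC convention, (-180, 180].

    Vectorised over any leading dimensions.
    """
    p0, p1, p2, p3 = (np.asarray(p) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    return np.where(ang == -180.0, 180.0, ang)


@dataclass
class DihedralSeries:
    """Per-frame, per-residue phi/psi in degrees; NaN marks undefined."""

    chain_id: str
    author_numbers: np.ndarray  # (R,)
    phi: np.ndarray             # (F, R)
    psi: np.ndarray             # (F, R)


def compute_phi_psi(traj: Trajectory, chain: str) -> DihedralSeries:
    """Backbone phi/psi series for one polymer chain.

    phi(i) = dihedral C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1).
    The first residue has no phi, the last no psi; a residue with a missing
    backbone atom (or a numbering gap to its neighbour) propagates NaN into
    the affected angles with a logged warning.
    """
    residues = traj.polymer_residues(chain)
    if not residues:
        raise ValueError(f"chain {chain!r} has no polymer residues")
    nres = len(residues)
    offsets = np.cumsum([0] + [len(r.atoms) for r in traj.residues])
    res_pos = {id(r): offsets[i] for i, r in enumerate(traj.residues)}

    idx = np.full((nres, 3), -1, dtype=int)  # N, CA, C
    for j, r in enumerate(residues):
        base = res_pos[id(r)]
        for k, name in enumerate(("N", "CA", "C")):
            ai = r.atom_index(name)
            if ai is None:
                log.warning("chain %s residue %d: missing backbone atom %s",
                            chain, r.author_number, name)
            else:
                idx[j, k] = base + ai
    numbers = np.array([r.author_number for r in residues])
    connected = np.diff(numbers) == 1  # chain-break detection by numbering

    F = traj.n_frames
    phi = np.full((F, nres), np.nan)
    psi = np.full((F, nres), np.nan)
    X = traj.coords

    have = idx >= 0
    for j in range(nres):
        if j > 0 and connected[j - 1] and have[j - 1, 2] and have[j].all():
            phi[:, j] = dihedral(X[:, idx[j - 1, 2]], X[:, idx[j, 0]],
                                 X[:, idx[j, 1]], X[:, idx[j, 2]])
        if (j < nres - 1 and connected[j] and have[j].all()
                and have[j + 1, 0]):
            psi[:, j] = dihedral(X[:, idx[j, 0]], X[:, idx[j, 1]],
                                 X[:, idx[j, 2]], X[:, idx[j + 1, 0]])
    return DihedralSeries(chain, numbers, phi, psi)


def rmsda(window, prototype) -> float:
    """RMSDA between an 8-angle window and a prototype (degrees).

    Returns NaN ("not assignable") if any window angle is undefined.
    """
    window = np.asarray(window, dtype=float)
    if window.shape[-1] != 8:
        raise ValueError("window must have 8 angles")
    if np.any(np.isnan(window)):
        return float("nan")
    d = wrap_degrees(window - np.asarray(prototype, dtype=float))
    return float(np.sqrt(np.mean(d ** 2)))


def dihedral_windows(series: DihedralSeries) -> np.ndarray:
    """(F, R, 8) assignment windows; NaN where incomplete.

    Window of residue i needs residues i-2..i+2, so the first and last two
    positions of a chain are never complete.
    """
    F, R = series.phi.shape
    win = np.full((F, R, 8), np.nan)
    if R >= 5:
        sl = slice(2, R - 2)
        win[:, sl, 0] = series.psi[:, 0:R - 4]
        win[:, sl, 1] = series.phi[:, 1:R - 3]
        win[:, sl, 2] = series.psi[:, 1:R - 3]
        win[:, sl, 3] = series.phi[:, 2:R - 2]
        win[:, sl, 4] = series.psi[:, 2:R - 2]
        win[:, sl, 5] = series.phi[:, 3:R - 1]
        win[:, sl, 6] = series.psi[:, 3:R - 1]
        win[:, sl, 7] = series.phi[:, 4:R]
    return win


@dataclass
class PBSequences:
    """Per-frame PB strings over one chain (``Z`` = not assignable)."""

    chain_id: str
    author_numbers: np.ndarray   # (R,)
    labels: np.ndarray           # (F, R) of single characters

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    def strings(self) -> list[str]:
        return ["".join(row) for row in self.labels]


def assign_pbs(series: DihedralSeries,
               table: np.ndarray | None = None) -> PBSequences:
    """Assign each residue in each frame to its nearest Protein Block.

    Nearest under RMSDA; ties break to the alphabetically lowest label.
    Incomplete windows yield ``Z``.  Deterministic and invariant under
    rigid-body motion (dihedrals are internal coordinates).
    """
    proto = PB_MATRIX if table is None else np.asarray(table, dtype=float)
    if proto.shape != (16, 8):
        raise ValueError("prototype table must be 16 x 8")
    win = dihedral_windows(series)
    F, R, _ = win.shape
    ok = ~np.isnan(win).any(axis=2)                    # (F, R)
    filled = np.where(ok[:, :, None], win, 0.0)        # placeholder, masked out
    cost = np.empty((F, R, 16))
    for k in range(16):
        d = wrap_degrees(filled - proto[k])
        cost[:, :, k] = np.sqrt(np.mean(d ** 2, axis=2))
    best = np.argmin(cost, axis=2)                     # first minimum = lexical
    letters = np.array(list(PB_LABELS))
    labels = np.where(ok, letters[best], NOT_ASSIGNED)
    return PBSequences(series.chain_id, series.author_numbers, labels)


def write_pb_strings(seqs: PBSequences, path, times_ps=None) -> None:
    """FASTA-like per-frame PB strings for interoperability with PB tooling."""
    with open(path, "w") as fh:
        for i, s in enumerate(seqs.strings()):
            t = "" if times_ps is None else f" time_ps={times_ps[i]:g}"
            fh.write(f">frame_{i} chain={seqs.chain_id}{t}\n{s}\n")


def read_pb_strings(path) -> list[str]:
    out, cur = [], None
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if ln.startswith(">"):
                if cur is not None:
                    out.append(cur)
                cur = ""
            elif ln:
                cur = (cur or "") + ln
    if cur:
        out.append(cur)
    return out
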