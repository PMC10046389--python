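"""Ground-truth ensemble generator.

Produces statistically controlled conformational ensembles that stand in for
MD trajectories: backbones are rebuilt from dihedrals with ideal covalent
geometry (NeRF internal-to-Cartesian construction), per-position Protein
Block mixtures are sampled with known probabilities, ions follow a scripted
binding schedule, and dimers either hold together or separate at a fixed
rate.  No force field, no solvent, no thermodynamics: the point is exact,
recoverable ground truth for every downstream statistic.

PB sampling design: a sampled block only controls the full 5-residue
assignment window when all 8 window dihedrals carry the prototype's values,
so mixture "probe" positions stamp the complete 8-angle window (jitter on
the central phi/psi pair only) and must be spaced at least 5 residues apart
to keep windows overlap-free.  The minimum pairwise prototype RMSDA is
~54 degrees, so with jitter <= 15 degrees (perturbation <= 7.5 degrees)
re-assignment recovers the sampled block exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .pb import PB_LABELS, PB_MATRIX, PB_REFERENCE_ANGLES
from .trajectory import AtomRecord, ResidueRecord, Trajectory

#: minimum author-number spacing between probe positions (window width)
PROBE_SPACING = 5

#: coil-like blocks used for flexible tails
COIL_PBS = "acdefghij"


@dataclass(frozen=True)
class GeometryParams:
    """Ideal backbone covalent geometry (lengths A, angles degrees)."""

    n_ca: float = 1.458
    ca_c: float = 1.525
    c_n: float = 1.329
    ang_n_ca_c: float = 111.2
    ang_ca_c_n: float = 116.6
    ang_c_n_ca: float = 121.7
    omega: float = 180.0

    def __post_init__(self):
        for v in (self.n_ca, self.ca_c, self.c_n):
            if v <= 0:
                raise ValueError("bond lengths must be positive")
        for a in (self.ang_n_ca_c, self.ang_ca_c_n, self.ang_c_n_ca):
            if not 0 < a < 180:
                raise ValueError("bond angles must be in (0, 180)")


@dataclass
class IonEvent:
    """Scripted ion: bound to *target* from *bind_frame* up to (excl.)
    *unbind_frame*; ``bind_frame=None`` means never bound."""

    target_author_number: int
    bind_frame: int | None = 0
    unbind_frame: int | None = None
    chain: str = "A"


@dataclass
class GroundTruth:
    """What the generator actually did, for downstream recovery checks."""

    seed: int
    stride_ps: float = 100.0
    pb_mixtures: dict[int, list[float]] = field(default_factory=dict)
    sampled_labels: dict[int, str] = field(default_factory=dict)
    rigid_positions: list[int] = field(default_factory=list)
    flexible_positions: list[int] = field(default_factory=list)
    ion_schedule: list[IonEvent] = field(default_factory=list)
    dimer_mode: dict | None = None

    def scheduled_occupancy(self, n_frames: int) -> dict[int, float]:
        """Target-residue occupancy implied by the ion schedule."""
        out: dict[int, float] = {}
        for ev in self.ion_schedule:
            if ev.bind_frame is None:
                continue
            stop = n_frames if ev.unbind_frame is None else min(ev.unbind_frame,
                                                                n_frames)
            frac = max(0, stop - ev.bind_frame) / n_frames
            out[ev.target_author_number] = max(
                out.get(ev.target_author_number, 0.0), frac)
        return out

    def to_json(self, path) -> None:
        d = asdict(self)
        d["pb_mixtures"] = {str(k): v for k, v in self.pb_mixtures.items()}
        d["sampled_labels"] = {str(k): v for k, v in self.sampled_labels.items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["pb_mixtures"] = {int(k): v for k, v in d["pb_mixtures"].items()}
        d["sampled_labels"] = {int(k): v for k, v in d["sampled_labels"].items()}
        d["ion_schedule"] = [IonEvent(**e) for e in d["ion_schedule"]]
        return cls(**d)


# -- internal-to-Cartesian construction -----------------------------------

def nerf(a, b, c, bond: float, angle_deg: float, torsion_deg):
    """Place atom x with |c-x| = bond, angle(b,c,x) = angle, and
    dihedral(a,b,c,x) = torsion.  Vectorised over leading dimensions."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(angle_deg)
    chi = np.radians(np.asarray(torsion_deg, dtype=float))[..., None]
    bc = c - b
    bc /= np.linalg.norm(bc, axis=-1, keepdims=True)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    d = np.concatenate([
        np.broadcast_to(-bond * np.cos(theta), chi.shape),
        bond * np.sin(theta) * np.cos(chi),
        bond * np.sin(theta) * np.sin(chi),
    ], axis=-1)
    return c + d[..., 0:1] * bc + d[..., 1:2] * m + d[..., 2:3] * n


def build_backbone(phi, psi, params: GeometryParams | None = None,
                   with_cb: bool = False) -> np.ndarray:
    """Backbone coordinates from per-residue phi/psi.

    ``phi``/``psi`` have shape ``(..., R)``; ``phi[..., 0]`` and
    ``psi[..., -1]`` are ignored (undefined at chain termini) but any NaN
    mid-chain is an error.  Atoms are returned in residue order as N, CA, C
    (plus a CB pseudo-atom per residue when ``with_cb``), shape
    ``(..., R*k, 3)``.  Recomputing phi/psi from the result reproduces the
    inputs.
    """
    params = params or GeometryParams()
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    if phi.shape != psi.shape:
        raise ValueError("phi and psi must have the same shape")
    F, R = phi.shape
    if R < 2:
        raise ValueError("need at least 2 residues")
    if np.isnan(phi[:, 1:]).any() or np.isnan(psi[:, :-1]).any():
        raise ValueError("undefined phi/psi mid-chain")

    th = np.radians(params.ang_n_ca_c)
    N = np.zeros((F, R, 3))
    CA = np.zeros((F, R, 3))
    C = np.zeros((F, R, 3))
    CA[:, 0] = [params.n_ca, 0.0, 0.0]
    C[:, 0] = CA[:, 0] + params.ca_c * np.array([-np.cos(th), np.sin(th), 0.0])
    for i in range(R - 1):
        N[:, i + 1] = nerf(N[:, i], CA[:, i], C[:, i],
                           params.c_n, params.ang_ca_c_n, psi[:, i])
        CA[:, i + 1] = nerf(CA[:, i], C[:, i], N[:, i + 1],
                            params.n_ca, params.ang_c_n_ca, params.omega)
        C[:, i + 1] = nerf(C[:, i], N[:, i + 1], CA[:, i + 1],
                           params.ca_c, params.ang_n_ca_c, phi[:, i + 1])
    atoms = [N, CA, C]
    if with_cb:
        # pseudo side-chain atom: fixed improper off the backbone frame
        CB = nerf(N, C, CA, 1.532, 110.6, np.full((F, R), 122.6))
        atoms.append(CB)
    out = np.stack(atoms, axis=2)           # (F, R, k, 3)
    return out.reshape(F, R * len(atoms), 3)


def _make_residues(n_res: int, chain: str, start_number: int,
                   with_cb: bool) -> list[ResidueRecord]:
    names = [("N", "N"), ("CA", "C"), ("C", "C")] + ([("CB", "C")] if with_cb else [])
    return [ResidueRecord(chain_id=chain, author_number=start_number + i,
                          name="ALA",
                          atoms=[AtomRecord(n, e) for n, e in names])
            for i in range(n_res)]


def trajectory_from_dihedrals(phi, psi, chain: str = "A",
                              start_number: int = 352,
                              stride_ps: float = 100.0,
                              with_cb: bool = True,
                              label: str = "synthetic",
                              params: GeometryParams | None = None) -> Trajectory:
    """Build a Trajectory from (F, R) phi/psi arrays."""
    coords = build_backbone(phi, psi, params=params, with_cb=with_cb)
    F, _, _ = coords.shape
    residues = _make_residues(phi.shape[1], chain, start_number, with_cb)
    times = np.arange(F, dtype=float) * stride_ps
    return Trajectory(residues, coords, times, label)


# -- PB-mixture sampling ---------------------------------------------------

def _central_angles(pb: str) -> tuple[float, float]:
    v = PB_REFERENCE_ANGLES[pb]
    return v[3], v[4]


def sample_system(n_res: int, mixtures: dict[int, "np.ndarray"],
                  n_frames: int = 1000, jitter_deg: float = 5.0,
                  seed: int = 0, background_pb: str = "m",
                  start_number: int = 352, stride_ps: float = 100.0,
                  label: str = "synthetic") -> tuple[Trajectory, GroundTruth]:
    """Ensemble with known per-position PB mixtures at probe positions.

    *mixtures* maps author numbers to 16-vectors over the PBs a..p.  Probes
    must sit at least two residues from each chain end and at least
    :data:`PROBE_SPACING` apart; each frame draws one block per probe and
    stamps its full 8-angle window, so re-assignment recovers the draw
    exactly (see module docstring).  All other positions carry the
    background block's central angles.  Uniform jitter of +-*jitter_deg* is
    applied to every position's own phi/psi except the stamped probe
    neighbourhoods, and to the probe's central pair.  Deterministic for a
    fixed seed.
    """
    if jitter_deg < 0:
        raise ValueError("jitter_deg must be >= 0")
    if jitter_deg > 15:
        raise ValueError("jitter_deg above 15 breaks exact PB recovery")
    rng = np.random.default_rng(seed)
    probes = sorted(mixtures)
    lo, hi = start_number, start_number + n_res - 1
    for p in probes:
        if not lo + 2 <= p <= hi - 2:
            raise ValueError(f"probe {p} too close to a chain end")
    for p, q in zip(probes, probes[1:]):
        if q - p < PROBE_SPACING:
            raise ValueError(f"probes {p} and {q} closer than {PROBE_SPACING}")
    mix = {}
    for p, v in mixtures.items():
        v = np.asarray(v, dtype=float)
        if v.shape != (16,) or (v < 0).any() or abs(v.sum() - 1) > 1e-9:
            raise ValueError(f"mixture at {p} is not a probability 16-vector")
        mix[p] = v

    bg_phi, bg_psi = _central_angles(background_pb)
    phi = np.full((n_frames, n_res), bg_phi)
    psi = np.full((n_frames, n_res), bg_psi)
    phi += rng.uniform(-jitter_deg, jitter_deg, phi.shape)
    psi += rng.uniform(-jitter_deg, jitter_deg, psi.shape)

    gt = GroundTruth(seed=seed, stride_ps=stride_ps,
                     pb_mixtures={p: mix[p].tolist() for p in probes})
    for p in probes:
        i = p - start_number
        draws = rng.choice(16, size=n_frames, p=mix[p])
        proto = PB_MATRIX[draws]                     # (F, 8)
        psi[:, i - 2] = proto[:, 0]
        phi[:, i - 1] = proto[:, 1]
        psi[:, i - 1] = proto[:, 2]
        phi[:, i] = proto[:, 3] + rng.uniform(-jitter_deg, jitter_deg, n_frames)
        psi[:, i] = proto[:, 4] + rng.uniform(-jitter_deg, jitter_deg, n_frames)
        phi[:, i + 1] = proto[:, 5]
        psi[:, i + 1] = proto[:, 6]
        phi[:, i + 2] = proto[:, 7]
        gt.sampled_labels[p] = "".join(PB_LABELS[k] for k in draws)

    traj = trajectory_from_dihedrals(phi, psi, start_number=start_number,
                                     stride_ps=stride_ps, label=label)
    return traj, gt


def make_helix_with_tails(core_len: int = 20, tail_len: int = 8,
                          n_frames: int = 300, jitter_deg: float = 5.0,
                          seed: int = 0, start_number: int = 352,
                          stride_ps: float = 100.0,
                          label: str = "helix_with_tails"
                          ) -> tuple[Trajectory, GroundTruth]:
    """Rigid helix core flanked by disordered tails.

    Core positions hold the helix block's angles (small jitter); each tail
    position redraws a coil block every frame, so downstream RMSF must rank
    tails above core.  ``tail_len=0`` gives a uniformly rigid helix.
    """
    rng = np.random.default_rng(seed)
    n_res = core_len + 2 * tail_len
    if core_len < 1 or n_res < 5:
        raise ValueError("system too small")
    m_phi, m_psi = _central_angles("m")
    phi = np.full((n_frames, n_res), m_phi)
    psi = np.full((n_frames, n_res), m_psi)
    tail_idx = list(range(tail_len)) + list(range(core_len + tail_len, n_res))
    coil = np.array([_central_angles(c) for c in COIL_PBS])
    for i in tail_idx:
        draws = rng.integers(0, len(COIL_PBS), size=n_frames)
        phi[:, i] = coil[draws, 0]
        psi[:, i] = coil[draws, 1]
    phi += rng.uniform(-jitter_deg, jitter_deg, phi.shape)
    psi += rng.uniform(-jitter_deg, jitter_deg, psi.shape)
    traj = trajectory_from_dihedrals(phi, psi, start_number=start_number,
                                     stride_ps=stride_ps, label=label)
    gt = GroundTruth(seed=seed, stride_ps=stride_ps,
                     rigid_positions=[start_number + tail_len + i
                                      for i in range(core_len)],
                     flexible_positions=[start_number + i for i in tail_idx])
    return traj, gt


# -- scripted ions ---------------------------------------------------------

def add_ions(traj: Trajectory, schedule: list[IonEvent], element: str = "Ca",
             seed: int = 0, bound_distance: float = 2.0,
             far_margin: float = 20.0) -> Trajectory:
    """Append one scripted ion per schedule entry.

    While bound, an ion sits exactly *bound_distance* A outward from a heavy
    atom (CB, else CA) of its target residue; while unbound it is parked
    outside the protein's bounding sphere plus *far_margin* (>= 15 A from
    every protein atom) in a per-ion fixed random direction.
    """
    rng = np.random.default_rng(seed)
    prot = np.flatnonzero(traj.atom_is_polymer)
    center = traj.coords[:, prot].mean(axis=1)                    # (F, 3)
    radius = np.linalg.norm(traj.coords[:, prot] - center[:, None], axis=2).max()

    residues = list(traj.residues)
    new_coords = [traj.coords]
    elem = element.capitalize()
    for k, ev in enumerate(schedule):
        sel_ca = np.flatnonzero((traj.atom_chain == ev.chain)
                                & (traj.atom_resnum == ev.target_author_number)
                                & (traj.atom_name == "CA"))
        sel_cb = np.flatnonzero((traj.atom_chain == ev.chain)
                                & (traj.atom_resnum == ev.target_author_number)
                                & (traj.atom_name == "CB"))
        if sel_ca.size == 0:
            raise ValueError(f"ion target residue {ev.target_author_number} "
                             f"not found on chain {ev.chain!r}")
        ca = traj.coords[:, sel_ca[0]]
        anchor = traj.coords[:, sel_cb[0]] if sel_cb.size else ca
        out_dir = anchor - ca
        nrm = np.linalg.norm(out_dir, axis=1, keepdims=True)
        fallback = rng.normal(size=3)
        fallback /= np.linalg.norm(fallback)
        out_dir = np.where(nrm > 1e-9, out_dir / np.maximum(nrm, 1e-9), fallback)
        bound_pos = anchor + bound_distance * out_dir
        far_dir = rng.normal(size=3)
        far_dir /= np.linalg.norm(far_dir)
        far_pos = center + (radius + far_margin) * far_dir

        pos = far_pos.copy()
        if ev.bind_frame is not None:
            stop = traj.n_frames if ev.unbind_frame is None else ev.unbind_frame
            sl = slice(ev.bind_frame, stop)
            pos[sl] = bound_pos[sl]
        residues.append(ResidueRecord(chain_id="X", author_number=k + 1,
                                      name=elem.upper(), hetero=True,
                                      atoms=[AtomRecord(elem.upper(), elem)]))
        new_coords.append(pos[:, None, :])
    out = Trajectory(residues, np.concatenate(new_coords, axis=1),
                     traj.times_ps.copy(), traj.label)
    return out


# -- dimers ----------------------------------------------------------------

def make_dimer(traj: Trajectory, mode: str = "stable",
               rate_A_per_frame: float = 1.0, start_frame: int = 0,
               initial_offset_A: float = 30.0, axis=(1.0, 0.0, 0.0),
               jitter_A: float = 0.05, seed: int = 0, chain: str = "A",
               new_chain: str = "B") -> tuple[Trajectory, GroundTruth]:
    """Duplicate *chain* as a second chain at a rigid offset.

    ``stable`` adds only a small rigid translation jitter per frame;
    ``separating`` additionally translates chain 2 along *axis* by
    *rate_A_per_frame* for every frame past *start_frame* (rate 0 degenerates
    to stable).  Ions and other chains of the input are kept unchanged.
    """
    if mode not in ("stable", "separating"):
        raise ValueError(f"unknown dimer mode {mode!r}")
    rng = np.random.default_rng(seed)
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    sel = np.flatnonzero((traj.atom_chain == chain) & traj.atom_is_polymer)
    if sel.size == 0:
        raise ValueError(f"no polymer chain {chain!r} to duplicate")
    F = traj.n_frames
    sep = np.zeros(F)
    if mode == "separating":
        sep = rate_A_per_frame * np.maximum(0, np.arange(F) - start_frame)
    shift = (initial_offset_A + sep)[:, None] * axis[None, :]
    shift = shift + rng.normal(scale=jitter_A, size=(F, 3)) if jitter_A else shift
    dup = traj.coords[:, sel] + shift[:, None, :]

    residues = list(traj.residues)
    for r in traj.residues:
        if r.is_polymer and r.chain_id == chain:
            residues.append(ResidueRecord(chain_id=new_chain,
                                          author_number=r.author_number,
                                          name=r.name, atoms=list(r.atoms),
                                          hetero=False))
    coords = np.concatenate([traj.coords, dup], axis=1)
    out = Trajectory(residues, coords, traj.times_ps.copy(),
                     f"{traj.label}_dimer_{mode}")
    gt = GroundTruth(seed=seed, dimer_mode={
        "mode": mode, "rate_A_per_frame": rate_A_per_frame,
        "start_frame": start_frame, "initial_offset_A": initial_offset_A})
    return out, gt
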