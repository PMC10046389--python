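# Methods

## Trajectory model

A trajectory couples an immutable topology (chains → residues → atoms, with
author residue numbering preserved end-to-end; the CALR C-domain uses the
352-based numbering of the full-length protein) with an ordered stack of
coordinate frames in Å and strictly increasing times in ps. Multi-model PDB
is the interchange format (one frame per MODEL block, parsed and written
through biotite); frame times travel in a `REMARK 100` header so round
trips are lossless, and default to a 100 ps stride — the usual save
interval for the production runs this tooling targets — when absent. Ion
records (HETATM) are kept as single-atom hetero residues whose element is
read from PDB columns 77–78 with an atom/residue-name fallback. Atom-name
selections apply to polymer residues only, so selecting `CA` yields
Cα atoms and can never catch a calcium ion (ions are selected by element).
Equilibration discard removes frames before a time cut, default 5000 ps.

## Protein Blocks assignment

The 16 prototype 8-vectors (ψ₋₂, φ₋₁, ψ₋₁, φ₀, ψ₀, φ₊₁, ψ₊₁, φ₊₂) are the
canonical Protein Blocks definition as distributed with the standard PB
assignment tooling, embedded as a constant. Their roles are enforced
behaviourally in the test suite: ideal helix dihedrals (φ=−57°, ψ=−47°)
assign to *m*, ideal extended-strand dihedrals (φ=−120°, ψ=+130°) to *d*,
and the minimum pairwise prototype RMSDA is ≈54° (between *m* and *n*).

φ/ψ are computed from N/CA/C positions with the IUPAC sign convention,
angles in (−180°, 180°]. Dissimilarity is RMSDA with shortest-arc wrapping;
ties break to the alphabetically lowest label (deterministic, matching
lexical iteration). A residue needs the full 5-residue window (residues
i−2…i+2 with all backbone atoms, no numbering gaps), so the first and last
two positions of every chain — and any position affected by missing
atoms — carry the sentinel `Z`. `Z` positions are **excluded** from
frequency statistics rather than counted as a 17th state, keeping
Σ_x f_x = 1 at every assignable position as the N_eq and ΔPB formulas
assume. Equivalently, the time-cut and window rules are implemented as two
independent filters (frames by time; terminal residues by window
completeness).

## Profile statistics

N_eq uses the natural logarithm (so exp inverts the Shannon entropy in
nats) with 0·ln 0 ≡ 0; it is cross-checked against an independent entropy
implementation in the tests. ΔN_eq and ΔPB align positions between systems
by author-number identity; an explicit pairing map can be supplied when
two systems of different lengths must be matched (the frameshifted tails
have no canonical residue correspondence, and identity-by-number is the
only reproducible default). Positions never assignable in either system
are dropped from comparisons with a logged note. Reports flag N_eq > 6 as
"disordered-like" and N_eq ≤ 2 as "rigid"; both thresholds are
configuration, not science.

## Flexibility

RMSD and RMSF are computed for Cα atoms only. Every frame is superposed on
the reference frame (least squares via scipy's Kabsch implementation,
proper rotation) before measuring. RMSD's reference is the first retained
frame after the equilibration cut; RMSF deviations are taken from each
atom's post-fit time-average position, in a single pass without iterative
mean refinement. A separate fit selection may be supplied — fitting on a
rigid core is the standard way to keep disordered termini from inflating
core fluctuations, and is what the ground-truth recovery tests use.

## Ion binding

Occupancy of a residue is the fraction of frames in which any ion of the
requested element lies within the cutoff (default 3.0 Å) of any of the
residue's heavy atoms (hydrogens excluded; coarse models often lack them).
Presence is binary per frame — ions are not counted per residue. Binding
onset is the earliest frame from which an ion stays within cutoff of the
protein for a persistence window, default 10 frames (1 ns at the 100 ps
stride); persistence of 1 would accept single-frame grazing contacts. No
periodic-boundary minimum-image handling is applied; synthetic ensembles
are generated unwrapped, and wrapped inputs must be imaged upstream.

## Dimer geometry

Anchor distances are Cα–Cα distances between same-numbered residues of the
two chains; the per-system anchor triplets used in the CALR dimer analyses
(e.g. 366/385/400 for class A) ship as defaults keyed by system label. A
dimer is "separated" when the minimum anchor distance stays above a
threshold (default 50 Å) for the final fraction of frames (default 20%);
the onset is the first frame of that terminal excursion. Published
separations reach ≈100–250 Å while stable dimers oscillate near contact,
so the defaults sit between the regimes; both are configuration recorded
in output provenance. Disulfide geometry is reported as the Sγ–Sγ distance,
falling back (flagged) to Cα–Cα when Sγ is absent.

## Sequence features

The wild-type CALR C-domain fragment (author residues 352–417 of UniProt
P27797, 66 residues, ending KDEL) is embedded as a constant. Substitutions
(p.XnY) and stops (p.Xn*) are applied directly; frameshift products carry
novel coding sequence that cannot be derived at protein level, so the
class A/B/C example sequences ship as fixtures. The shipped A/B/C files
are **synthetic stand-ins** (marked as such in file and docstrings): exact
wild-type prefix up to the frameshift start, plus a constructed basic tail
reproducing the published fragment length, net charge, KDEL loss and
terminal CREAC motif with its two cysteines. Classes D (p.E389*) and E
(p.L367I) are derived exactly from the wild-type fragment.

Net formal charge is (#K + #R) − (#D + #E), His neutral, termini ignored —
the convention under which the wild-type fragment scores −26. Counter-ion
counts are ⌈|q|/valence⌉ with species chosen by sign (divalent Ca²⁺ or
monovalent Na⁺ for acidic systems, Cl⁻ for basic ones): −26 → 13 Ca²⁺ or
26 Na⁺. The CREAC motif must fall within the final 10 residues
(configurable window), and disulfide-mediated dimer capability is equated
with its presence. Helix content is interval-based (inclusive author-number
ranges, rounded half-up to integer %). Note: only the class A helix
interval (366–388 over 60 residues → 38%) reproduces the published helix
percentage; the documented helix boundaries for wt, B, C and D give
different percentages than the published table (e.g. B: 84% from the
printed boundaries vs 55% reported), so the bundled intervals reproduce the
printed *boundaries* and the discrepancy is left visible rather than
resolved.

## Synthetic-data generator

The generator emulates the *statistical* structure of the studied systems —
rigid helix cores, disordered termini, scripted Ca²⁺ binding, dimers that
hold or separate — with exact, recorded ground truth. It is not physics:
no force field, no solvent, no realistic kinetics, and passing recovery
tests demonstrates correctness of the analysis pipeline, not fidelity of
any MD engine.

Backbones are constructed residue-by-residue from φ/ψ with NeRF
internal-to-Cartesian placement and ideal geometry (N–Cα 1.458 Å, Cα–C
1.525 Å, C–N 1.329 Å; angles 111.2°/116.6°/121.7°; ω = 180°), giving the
standard ≈3.8 Å trans-peptide Cα spacing; recomputing dihedrals from the
output reproduces the inputs to < 1e-6°. A Cβ pseudo-atom is added at a
fixed improper so residues have an off-backbone heavy atom for ion
targeting.

PB-mixture sampling stamps the **full 8-angle window** of the drawn
prototype at each probe position. Stamping only the central (φ₀, ψ₀) was
tried first and fails: six of the eight window angles then come from the
context, whose contribution dominates the RMSDA, and assignment collapses
to the context block regardless of the draw. With full-window stamping,
probes spaced ≥ 5 residues apart (overlap-free windows) and uniform jitter
≤ 15° on the central pair (RMSDA perturbation ≤ jitter/2, far below the
≈27° half-distance between the closest prototypes), re-assignment recovers
every draw exactly — the recovery tests assert label-level identity, and
empirical frequency error is pure binomial noise. Positions within ±2 of a
probe are contaminated by construction and carry no ground-truth claim.
Jitter is uniform for simplicity rather than von Mises.

The helix-with-tails system (defaults: 20-residue pure-*m* core, 8-residue
tails redrawing a coil block every frame, 5° jitter, 300 frames) grounds
the flexibility tests: with superposition on the rigid core, tail RMSF
exceeds core RMSF by an order of magnitude, and the Spearman correlation
between RMSF and the graded ground-truth flexibility (distance outside the
core, 0 within) reaches the value attained under perfect rank recovery
(≈0.91; exact 1 is unattainable because all core positions tie in the
ground truth). Scripted ions sit exactly 2.0 Å outward from their target's
Cβ while bound and are parked outside the protein's bounding sphere plus
20 Å while unbound, so scheduled occupancies are recovered exactly on
rigid systems (disordered tails can graze a bound ion, which is physical
contact, not a bookkeeping error). Dimers duplicate the chain at a rigid
offset; separation translates chain 2 linearly from a start frame, and a
rate of 0 degenerates to the stable mode.

## Problem sizes and determinism

The validation suite uses 2000-frame ensembles for sampling checks and a
single 5000-frame ensemble for the mixture-recovery tolerance (total
variation < 0.05, N_eq within 0.1 of exp H), 300 frames for flexibility
ranking, and 40–200 frames for scripted ion/dimer scenarios — sizes chosen
so the controlled statistics are well inside their tolerances. All
randomness flows through seeded `numpy` generators; identical seeds and
parameters produce byte-identical output files, and every TSV carries a
provenance header (version, config hash, parameters).

## Known limitations

* No periodic-boundary imaging, no solvent or ion chemistry, no energetics.
* Frequency profiles are unsmoothed and no significance test accompanies
  ΔPB (none is defined for it).
* Assignment near chain breaks depends on author-number gaps to detect
  discontinuity; renumbered-but-broken chains would be treated as
  continuous.
* The synthetic frameshift sequences are feature-matched stand-ins, not
  the database entries they emulate; analyses that depend on the literal
  novel-tail residue order should supply real sequences via FASTA.
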