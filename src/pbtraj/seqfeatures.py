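"""Sequence-level features of calreticulin C-domain variants.

The wild-type C-domain is the acidic 66-residue fragment spanning author
residues 352-417 of human calreticulin (UniProt P27797), ending in the ER
retention signal KDEL.  Essential-thrombocythemia variants fall into five
classes: frameshifts (A, B, C) that replace the acidic tail with a basic,
cysteine-bearing one (CREAC motif, enabling disulfide-linked dimers), a
truncation (D, p.E389*), and a point substitution (E, p.L367I).  This module
derives the per-variant feature table: fragment length, KDEL presence, net
formal charge, helix content, cysteines/CREAC, dimer capability, and the
counter-ion species/count needed to neutralise a simulation box.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from math import ceil, floor

import pandas as pd
from Bio import SeqIO

#: author number of the first C-domain residue
CDOMAIN_START = 352

#: human calreticulin C-domain, residues 352-417 of UniProt P27797
WT_CDOMAIN = "AAEKQMKDKQDEEQRLKEEEEDKKRKEEEEAEDKEDDEDKDEDEEDEEDKEEDEEEDVPGQAKDEL"

VARIANT_NOTATIONS = {
    "A": "p.L367Tfs*46",
    "B": "p.K385Nfs*47",
    "C": "p.E380Dfs*51",
    "D": "p.E389*",
    "E": "p.L367I",
}

#: helix annotations as author-number intervals (inclusive).  Only the class
#: A interval reproduces the published helix percentage exactly (23/60 ->
#: 38%); see the methods note for the others.
DEFAULT_HELIX_INTERVALS: dict[str, list[tuple[int, int]]] = {
    "wt": [(353, 386)],
    "A": [(366, 388)],
    "B": [(354, 374), (379, 414), (417, 425)],
    "C": [(384, 406)],
    "D": [(353, 386)],
    "E": [(352, 386)],
}

_CREAC_WINDOW = 10  # motif must fall within this many terminal residues

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class VariantRecord:
    id: str
    class_label: str          # wt | A | B | C | D | E
    notation: str
    sequence: str
    start: int = CDOMAIN_START

    def __post_init__(self):
        bad = set(self.sequence) - _AA
        if bad:
            raise ValueError(f"{self.id}: non-standard residues {sorted(bad)}")


_SUB_RE = re.compile(r"^p\.([A-Z])(\d+)([A-Z]|\*)$")


def apply_simple_variant(wt_seq: str, notation: str,
                         start: int = CDOMAIN_START) -> str:
    """Apply a substitution (p.XnY) or stop (p.Xn*) to a fragment.

    Positions use author numbering; a stop at n truncates so the last
    retained residue is n-1.  Frameshift products carry novel sequence that
    cannot be derived at protein level and must be supplied explicitly.
    """
    m = _SUB_RE.match(notation)
    if not m:
        raise ValueError(
            f"unsupported notation {notation!r}: only simple substitutions "
            "and stops are derivable; supply frameshift products as sequences")
    ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    i = pos - start
    if not 0 <= i < len(wt_seq):
        raise ValueError(f"{notation}: position {pos} outside fragment "
                         f"{start}-{start + len(wt_seq) - 1}")
    if wt_seq[i] != ref:
        raise ValueError(f"{notation}: expected {ref} at {pos}, fragment has "
                         f"{wt_seq[i]}")
    if alt == "*":
        if i == 0:
            raise ValueError(f"{notation}: stop at first residue leaves an "
                             "empty fragment")
        return wt_seq[:i]
    return wt_seq[:i] + alt + wt_seq[i + 1:]


def net_formal_charge(seq: str) -> int:
    """(#K + #R) - (#D + #E); His neutral, termini ignored."""
    return (seq.count("K") + seq.count("R")) - (seq.count("D") + seq.count("E"))


_ION_VALENCE = {"Ca2+": 2, "Na+": 1, "Cl-": -1}


def counterion_requirement(charge: int, ion: str) -> int:
    """Ions of *ion* needed to neutralise *charge* (0 if the sign matches).

    A -26 fragment takes 13 Ca2+ or 26 Na+; positive fragments take Cl-.
    """
    if ion not in _ION_VALENCE:
        raise ValueError(f"unknown ion {ion!r}; expected one of {sorted(_ION_VALENCE)}")
    v = _ION_VALENCE[ion]
    if charge == 0 or charge * v > 0:
        return 0
    return ceil(abs(charge) / abs(v))


def default_counterion(charge: int, divalent: bool = True) -> tuple[str, int]:
    """Counter-ion species by charge sign (cations for acidic fragments,
    chloride for basic ones) and the count to neutralise."""
    if charge < 0:
        ion = "Ca2+" if divalent else "Na+"
    elif charge > 0:
        ion = "Cl-"
    else:
        return ("none", 0)
    return ion, counterion_requirement(charge, ion)


def detect_kdel(seq: str) -> bool:
    """True iff the fragment terminates in the ER retention signal KDEL."""
    return seq.endswith("KDEL")


def detect_creac_cysteines(seq: str,
                           window: int = _CREAC_WINDOW) -> tuple[int, bool]:
    """(total cysteine count, CREAC motif within the final *window* residues)."""
    return seq.count("C"), "CREAC" in seq[-window:]


def helix_fraction(helix_intervals, length: int) -> int:
    """Percent of residues inside the (inclusive, non-overlapping) helix
    intervals, rounded half-up to an integer."""
    ivs = sorted((int(a), int(b)) for a, b in helix_intervals)
    total = 0
    prev_end = None
    for a, b in ivs:
        if b < a:
            raise ValueError(f"invalid interval ({a}, {b})")
        if prev_end is not None and a <= prev_end:
            raise ValueError(f"overlapping helix intervals at {a}")
        total += b - a + 1
        prev_end = b
    if total > length:
        raise ValueError("helix intervals exceed fragment length")
    return int(floor(100.0 * total / length + 0.5))


@dataclass
class FeatureRow:
    system: str
    length: int
    has_kdel: bool
    net_charge: int
    helix_percent: int | None
    n_cys: int
    has_creac: bool
    dimer_capable: bool           # disulfide-mediated: requires CREAC cysteines
    counterion_species: str
    counterion_count: int


def variant_features(v: VariantRecord,
                     helix_intervals=None) -> FeatureRow:
    seq = v.sequence
    q = net_formal_charge(seq)
    n_cys, creac = detect_creac_cysteines(seq)
    ion, count = default_counterion(q)
    helix = None
    if helix_intervals:
        # intervals within [start, start+len-1]; clip check
        for a, b in helix_intervals:
            if a < v.start or b > v.start + len(seq) - 1:
                raise ValueError(
                    f"{v.id}: helix interval ({a},{b}) outside fragment")
        helix = helix_fraction(helix_intervals, len(seq))
    return FeatureRow(system=v.id, length=len(seq), has_kdel=detect_kdel(seq),
                      net_charge=q, helix_percent=helix, n_cys=n_cys,
                      has_creac=creac, dimer_capable=creac,
                      counterion_species=ion, counterion_count=count)


def build_feature_table(variants, helix_annotations=None) -> pd.DataFrame:
    """One feature row per variant, in the published column order."""
    helix_annotations = helix_annotations or {}
    rows = []
    for v in variants:
        ann = helix_annotations.get(v.class_label) or helix_annotations.get(v.id)
        rows.append(vars(variant_features(v, ann)))
    return pd.DataFrame(rows)


def _load_synthetic_frameshifts() -> dict[str, str]:
    ref = resources.files("pbtraj.data") / "synthetic_calr_frameshift_classes.fasta"
    with resources.as_file(ref) as path:
        seqs = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            cls = dict(tok.split("=", 1) for tok in rec.description.split()
                       if "=" in tok)["class"]
            seqs[cls] = str(rec.seq)
    return seqs


def builtin_variants() -> list[VariantRecord]:
    """The six studied systems: wild type plus the five class examples.

    wt, D and E are exact (D and E derived from the wild-type fragment by
    :func:`apply_simple_variant`); the frameshift classes A, B and C ship as
    synthetic stand-in sequences that reproduce the published length, charge,
    KDEL loss and CREAC features of their class examples.
    """
    out = [VariantRecord("CALRwt", "wt", "", WT_CDOMAIN)]
    fs = _load_synthetic_frameshifts()
    for cls in ("A", "B", "C"):
        out.append(VariantRecord(f"CALRm_{cls}", cls, VARIANT_NOTATIONS[cls],
                                 fs[cls]))
    for cls in ("D", "E"):
        seq = apply_simple_variant(WT_CDOMAIN, VARIANT_NOTATIONS[cls])
        out.append(VariantRecord(f"CALRm_{cls}", cls, VARIANT_NOTATIONS[cls], seq))
    return out


def read_variants_fasta(path) -> list[VariantRecord]:
    """Variants from FASTA; ``class=`` and ``notation=`` may be set in the
    description, otherwise the class defaults to the record id."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        meta = dict(tok.split("=", 1) for tok in rec.description.split()
                    if "=" in tok)
        out.append(VariantRecord(rec.id, meta.get("class", rec.id),
                                 meta.get("notation", ""), str(rec.seq)))
    return out
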