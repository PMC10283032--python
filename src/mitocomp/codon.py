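"""Codon usage, amino-acid usage and relative synonymous codon usage (RSCU)
under the vertebrate mitochondrial genetic code.

RSCU_ij = x_ij / ((1/n_i) Σ_j x_ij): the observed count of codon j in
synonymous family i divided by the count expected if all n_i codons of the
family were used equally.  Values above 1 mark positively biased codons;
above 1.6 overrepresented, below 0.6 underrepresented.

The vertebrate mitochondrial code differs from the standard code in that
AGA/AGG are stops, ATA is Met and TGA is Trp, so Leu keeps a 6-codon family
(UUR + CUN) while Ser has 6 (UCN + AGY) and the stop family has 4 members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import pandas as pd
from Bio.Data import CodonTable

from .errors import ValidationError

_VMITO = CodonTable.unambiguous_dna_by_id[2]  # vertebrate mitochondrial

ALL_CODONS: tuple[str, ...] = tuple("".join(c) for c in product("TCAG", repeat=3))
STOP_CODONS: frozenset[str] = frozenset(_VMITO.stop_codons)  # TAA TAG AGA AGG

#: codon -> one-letter amino acid, or "*" for the stop family
CODON_TO_AA: dict[str, str] = {
    c: ("*" if c in STOP_CODONS else _VMITO.forward_table[c]) for c in ALL_CODONS
}

#: family id (one-letter aa or "*") -> sorted synonymous codon tuple
FAMILIES: dict[str, tuple[str, ...]] = {}
for _c, _aa in CODON_TO_AA.items():
    FAMILIES.setdefault(_aa, ())
FAMILIES = {
    aa: tuple(sorted(c for c in ALL_CODONS if CODON_TO_AA[c] == aa))
    for aa in FAMILIES
}

AA_NAMES = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Stop",
}


@dataclass
class CodonUsageTable:
    counts: dict[str, int]
    total_codons: int
    includes_stops: bool
    dropped_trailing: int = 0
    dropped_ambiguous: int = 0
    families: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(FAMILIES))


@dataclass
class RscuProfile:
    rscu: dict[str, float]
    bias_class: dict[str, str]


def codon_counts(cds_seqs: list[str], include_stops: bool = True) -> CodonUsageTable:
    """Count codons over coding-strand CDS sequences read in frame 0.

    Trailing incomplete codons (the TA-/T-- cases) are dropped and tallied in
    ``dropped_trailing`` (bases); codons containing ambiguous bases are
    dropped and tallied in ``dropped_ambiguous`` (codons).  With
    ``include_stops=False`` the four vertebrate-mito stop codons are excluded.
    """
    if not cds_seqs:
        raise ValidationError("codon_counts: empty CDS list")
    counts = {c: 0 for c in ALL_CODONS}
    dropped_trailing = dropped_ambiguous = total = 0
    for seq in cds_seqs:
        seq = seq.upper()
        usable = len(seq) - (len(seq) % 3)
        dropped_trailing += len(seq) - usable
        for i in range(0, usable, 3):
            codon = seq[i : i + 3]
            if codon not in counts:
                dropped_ambiguous += 1
                continue
            if not include_stops and codon in STOP_CODONS:
                continue
            counts[codon] += 1
            total += 1
    return CodonUsageTable(counts, total, include_stops,
                           dropped_trailing, dropped_ambiguous)


def classify_rscu(value: float) -> str:
    if value > 1.6:
        return "overrepresented"
    if value > 1.0:
        return "positive"
    if value == 1.0:
        return "unbiased"
    if value >= 0.6:
        return "negative"
    return "underrepresented"


def rscu(t: CodonUsageTable) -> RscuProfile:
    """Per-codon RSCU and bias class.

    Families with zero total usage get RSCU 0 and class ``unused-family``.
    Within every used family the RSCU values sum to the family size n_i.
    """
    values: dict[str, float] = {}
    classes: dict[str, str] = {}
    for fam, codons in t.families.items():
        if not t.includes_stops and fam == "*":
            continue
        fam_total = sum(t.counts.get(c, 0) for c in codons)
        n_i = len(codons)
        for c in codons:
            if fam_total == 0:
                values[c] = 0.0
                classes[c] = "unused-family"
            else:
                values[c] = t.counts.get(c, 0) / (fam_total / n_i)
                classes[c] = classify_rscu(values[c])
    return RscuProfile(values, classes)


def amino_acid_counts(t: CodonUsageTable) -> dict:
    """Counts pooled per amino acid over each synonymous family.

    Returns ``{"counts": {aa3: int}, "most_frequent": aa3|None,
    "least_frequent": aa3|None, "tie": bool}``; the stop family is excluded
    from the ranking, ties broken alphabetically and flagged.
    """
    pooled: dict[str, int] = {}
    for fam, codons in t.families.items():
        if fam == "*":
            continue
        pooled[AA_NAMES[fam]] = sum(t.counts.get(c, 0) for c in codons)
    nonzero = {aa: n for aa, n in pooled.items() if n > 0}
    if not nonzero:
        return {"counts": {}, "most_frequent": None, "least_frequent": None,
                "tie": False}
    hi = max(nonzero.values())
    lo = min(nonzero.values())
    top = sorted(aa for aa, n in nonzero.items() if n == hi)
    bottom = sorted(aa for aa, n in nonzero.items() if n == lo)
    return {
        "counts": pooled,
        "most_frequent": top[0],
        "least_frequent": bottom[0],
        "tie": len(top) > 1 or len(bottom) > 1,
    }


def rscu_table(t: CodonUsageTable) -> pd.DataFrame:
    """Long-format table (64 rows): codon, amino acid, count, RSCU, class."""
    profile = rscu(t)
    rows = [
        {
            "codon": c,
            "amino_acid": AA_NAMES[CODON_TO_AA[c]],
            "count": t.counts.get(c, 0),
            "rscu": profile.rscu.get(c),
            "bias_class": profile.bias_class.get(c),
        }
        for c in ALL_CODONS
    ]
    return pd.DataFrame(rows)
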