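"""Base composition, A+T richness and strand-asymmetry (skew) statistics.

AT-skew = (A − T)/(A + T) and GC-skew = (G − C)/(G + C) measure which of the
two complementary bases dominates a strand; vertebrate mitogenomes typically
show a weakly positive AT-skew and a clearly negative GC-skew on the heavy
(majority) strand.  Statistics are computed for the whole majority strand,
for the standard partitions (concatenated protein-coding genes, rRNAs, tRNAs,
control region), per codon position within protein-coding genes, and per gene.

Ambiguity codes (N and friends) are counted separately and excluded from every
percentage and skew denominator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError
from .io import Mitogenome, extract_gene_sequence

_IUPAC = set("ACGTUNRYSWKMBDHV")
_AMBIG = _IUPAC - set("ACGTU")


@dataclass
class BaseCounts:
    a: int = 0
    c: int = 0
    g: int = 0
    t: int = 0
    ambiguous: int = 0

    @property
    def unambiguous(self) -> int:
        return self.a + self.c + self.g + self.t

    @property
    def total(self) -> int:
        return self.unambiguous + self.ambiguous

    def __add__(self, other: "BaseCounts") -> "BaseCounts":
        return BaseCounts(self.a + other.a, self.c + other.c, self.g + other.g,
                          self.t + other.t, self.ambiguous + other.ambiguous)


@dataclass
class CompositionRecord:
    """Composition summary for one named region (a Table-2-style cell group)."""

    region_label: str
    counts: BaseCounts
    at_percent: float | None
    at_skew: float | None
    gc_skew: float | None
    base_percents: dict[str, float] = field(default_factory=dict)


def count_bases(seq: str) -> BaseCounts:
    """Exact base counts; case-insensitive, U counted as T, IUPAC ambiguity
    codes pooled into ``ambiguous``."""
    seq = seq.upper()
    bad = set(seq) - _IUPAC
    if bad:
        raise ValidationError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return BaseCounts(
        a=seq.count("A"),
        c=seq.count("C"),
        g=seq.count("G"),
        t=seq.count("T") + seq.count("U"),
        ambiguous=sum(seq.count(x) for x in _AMBIG),
    )


def skews(counts: BaseCounts) -> tuple[float | None, float | None]:
    """(AT-skew, GC-skew) = ((A−T)/(A+T), (G−C)/(G+C)); None when undefined."""
    at = counts.a + counts.t
    gc = counts.g + counts.c
    at_skew = (counts.a - counts.t) / at if at else None
    gc_skew = (counts.g - counts.c) / gc if gc else None
    return at_skew, gc_skew


def composition_record(label: str, seq: str) -> CompositionRecord:
    counts = count_bases(seq)
    at_skew, gc_skew = skews(counts)
    n = counts.unambiguous
    if n:
        at_percent = 100.0 * (counts.a + counts.t) / n
        base_percents = {b: 100.0 * getattr(counts, b.lower()) / n
                         for b in ("T", "C", "A", "G")}
    else:
        at_percent = None
        base_percents = {}
    return CompositionRecord(label, counts, at_percent, at_skew, gc_skew,
                             base_percents)


_PARTITIONS = (
    ("Mito", None),
    ("PCGs", ("CDS",)),
    ("rRNAs", ("rRNA",)),
    ("tRNAs", ("tRNA",)),
    ("D-loop", ("D-loop",)),
)


def partition_stats(g: Mitogenome) -> list[CompositionRecord]:
    """Composition records for the whole majority strand and the standard
    partitions (concatenated CDS, rRNAs, tRNAs, D-loop).

    Partition sequences are majority-strand slices concatenated in genome
    order — the convention under which published whole-genome tables are
    computed — so light-strand genes are *not* re-oriented here (contrast
    :func:`per_gene_profile`).  Empty partitions are omitted with a warning.
    """
    if not g.features:
        raise ValidationError(f"{g.accession}: genome has no annotated features")
    out = []
    for label, types in _PARTITIONS:
        if types is None:
            seq = g.sequence
        else:
            parts = [
                _majority_slice(g, f) for f in g.features if f.type in types
            ]
            seq = "".join(parts)
        if not seq:
            warnings.warn(
                f"{g.accession}: partition {label!r} is empty and was omitted",
                stacklevel=2,
            )
            continue
        out.append(composition_record(label, seq))
    return out


def _majority_slice(g: Mitogenome, f) -> str:
    if f.wraps_origin:
        return g.sequence[f.start:] + g.sequence[: f.end]
    return g.sequence[f.start : f.end]


@dataclass
class CodonPositionComposition:
    """Base percentages and A+T% per codon position (1, 2, 3) and pooled."""

    positions: dict[str, dict[str, float]]  # "1"|"2"|"3"|"pooled" -> base %
    at_percent: dict[str, float]
    counts: dict[str, BaseCounts]


def codon_position_composition(cds_seqs: list[str]) -> CodonPositionComposition:
    """Pool bases by codon position across coding-strand CDS sequences.

    Trailing incomplete terminal codons (1–2 bases) are dropped per gene
    before pooling; percentages are over unambiguous bases.
    """
    if not cds_seqs:
        raise ValidationError("codon_position_composition: empty CDS list")
    pos_counts = {p: BaseCounts() for p in ("1", "2", "3")}
    for seq in cds_seqs:
        if len(seq) < 3:
            raise ValidationError(f"CDS shorter than one codon: {seq!r}")
        usable = len(seq) - (len(seq) % 3)
        for p in range(3):
            pos_counts[str(p + 1)] += count_bases(seq[p:usable:3])
    pos_counts["pooled"] = (pos_counts["1"] + pos_counts["2"] + pos_counts["3"])

    positions, at_percent = {}, {}
    for key, counts in pos_counts.items():
        n = counts.unambiguous
        if n == 0:
            continue
        positions[key] = {b: 100.0 * getattr(counts, b.lower()) / n
                          for b in ("T", "C", "A", "G")}
        at_percent[key] = 100.0 * (counts.a + counts.t) / n
    return CodonPositionComposition(positions, at_percent, pos_counts)


def per_gene_profile(g: Mitogenome) -> pd.DataFrame:
    """Per-gene composition in coding-strand orientation, ordered by genome
    position (the control region uses the majority strand).

    Returns a DataFrame with columns: gene, type, strand, length, a, c, g, t,
    ambiguous, at_percent, at_skew, gc_skew.
    """
    rows = []
    for f in g.features:
        if f.type == "other":
            continue
        seq = (extract_gene_sequence(g, f) if f.type != "D-loop"
               else _majority_slice(g, f))
        rec = composition_record(f.canonical_name, seq)
        rows.append({
            "gene": f.canonical_name,
            "type": f.type,
            "strand": f.strand,
            "length": f.length(g.length),
            "a": rec.counts.a, "c": rec.counts.c,
            "g": rec.counts.g, "t": rec.counts.t,
            "ambiguous": rec.counts.ambiguous,
            "at_percent": rec.at_percent,
            "at_skew": rec.at_skew,
            "gc_skew": rec.gc_skew,
        })
    return pd.DataFrame(rows)


def standard_error_of_proportion(p: float, n: int) -> float:
    """Binomial standard error sqrt(p(1-p)/n); handy for recovery checks."""
    return math.sqrt(p * (1.0 - p) / n)
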