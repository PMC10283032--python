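"""Gene order, strand assignment, start/stop codon classes and spacers.

The typical vertebrate mitogenome carries 37 genes (13 protein-coding, 22
tRNA, 2 rRNA) plus the control region (D-loop) and the light-strand
replication origin (OL) in a deeply conserved order, read clockwise from
tRNA-Phe.  ND6 and eight tRNAs sit on the light strand.  Three conserved
tRNA runs — IQM (Ile-Gln-Met), WANCY (Trp-Ala-Asn-Cys-Tyr, with OL tucked
between Asn and Cys) and HSL (His-Ser-Leu) — punctuate the coding genes.
Protein-coding genes frequently end in incomplete stop codons (TA-, T--)
when a same-strand tRNA follows; polyadenylation completes them to TAA.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError
from .io import GeneFeature, Mitogenome, extract_gene_sequence

#: (canonical_name, strand) in typical vertebrate order, anchored at tRNA-Phe.
CANONICAL_ORDER: tuple[tuple[str, str], ...] = (
    ("tRNA-Phe", "heavy"),
    ("12S", "heavy"),
    ("tRNA-Val", "heavy"),
    ("16S", "heavy"),
    ("tRNA-Leu(UUR)", "heavy"),
    ("ND1", "heavy"),
    ("tRNA-Ile", "heavy"),
    ("tRNA-Gln", "light"),
    ("tRNA-Met", "heavy"),
    ("ND2", "heavy"),
    ("tRNA-Trp", "heavy"),
    ("tRNA-Ala", "light"),
    ("tRNA-Asn", "light"),
    ("OL", "heavy"),
    ("tRNA-Cys", "light"),
    ("tRNA-Tyr", "light"),
    ("COI", "heavy"),
    ("tRNA-Ser(UCN)", "light"),
    ("tRNA-Asp", "heavy"),
    ("COII", "heavy"),
    ("tRNA-Lys", "heavy"),
    ("ATPase8", "heavy"),
    ("ATPase6", "heavy"),
    ("COIII", "heavy"),
    ("tRNA-Gly", "heavy"),
    ("ND3", "heavy"),
    ("tRNA-Arg", "heavy"),
    ("ND4L", "heavy"),
    ("ND4", "heavy"),
    ("tRNA-His", "heavy"),
    ("tRNA-Ser(AGY)", "heavy"),
    ("tRNA-Leu(CUN)", "heavy"),
    ("ND5", "heavy"),
    ("ND6", "light"),
    ("tRNA-Glu", "light"),
    ("CYTB", "heavy"),
    ("tRNA-Thr", "heavy"),
    ("tRNA-Pro", "light"),
    ("D-loop", "heavy"),
)

CANONICAL_LIGHT_STRAND: frozenset[str] = frozenset(
    name for name, strand in CANONICAL_ORDER
    if strand == "light" and name not in ("OL", "D-loop")
)

_CLUSTERS = {
    "IQM": ("tRNA-Ile", "tRNA-Gln", "tRNA-Met"),
    "WANCY": ("tRNA-Trp", "tRNA-Ala", "tRNA-Asn", "tRNA-Cys", "tRNA-Tyr"),
    "HSL": ("tRNA-His", "tRNA-Ser(AGY)", "tRNA-Leu(CUN)"),
}


@dataclass
class GeneOrderReport:
    observed: list[tuple[str, str]]
    matches_canonical: bool
    differences: list[tuple[int, tuple[str, str] | None, tuple[str, str] | None]]
    clusters_found: set[str]
    light_strand_set: set[str]
    anchored: bool  # False when tRNA-Phe was missing and a fallback rotation used


@dataclass
class CodonReport:
    gene: str
    strand: str
    start_codon: str
    stop_codon: str  # padded with '-' to 3 characters when incomplete
    stop_class: str  # "complete" | "incomplete"
    downstream_same_strand_trna: bool
    majority_start: str | None = None  # light-strand CDS only
    majority_stop: str | None = None


@dataclass
class SpacerOverlap:
    upstream: str
    downstream: str
    length: int  # >0 spacer, <0 overlap, 0 abutting
    strands: tuple[str, str]


def _ordered_elements(g: Mitogenome) -> list[GeneFeature]:
    return [f for f in g.features if f.type != "other"]


def gene_order(g: Mitogenome) -> GeneOrderReport:
    """Compare the observed gene arrangement with the canonical vertebrate
    order, rotation-invariantly, anchored at tRNA-Phe.

    Cluster detection requires members strictly adjacent in order; the
    noncoding elements (OL, D-loop) are transparent to adjacency, which is
    what lets WANCY span its embedded OL.
    """
    elements = _ordered_elements(g)
    observed = [(f.canonical_name, f.strand) for f in elements]
    if len(elements) < 2:  # degenerate record: report, no clusters
        light = {n for n, s in observed if s == "light"}
        return GeneOrderReport(observed, False, _diff(observed), set(),
                               light, anchored=False)

    names = [n for n, _ in observed]
    anchored = "tRNA-Phe" in names
    if anchored:
        k = names.index("tRNA-Phe")
    else:
        k = min(range(len(observed)), key=lambda i: observed[i:] + observed[:i])
    observed = observed[k:] + observed[:k]

    differences = _diff(observed)
    clusters = _find_clusters([n for n, _ in observed])
    light = {n for n, s in observed if s == "light" and n not in ("OL", "D-loop")}
    return GeneOrderReport(observed, not differences, differences, clusters,
                           light, anchored)


def _diff(observed) -> list:
    out = []
    for i in range(max(len(observed), len(CANONICAL_ORDER))):
        exp = CANONICAL_ORDER[i] if i < len(CANONICAL_ORDER) else None
        obs = observed[i] if i < len(observed) else None
        if exp != obs:
            out.append((i, exp, obs))
    return out


def _find_clusters(names: list[str]) -> set[str]:
    # noncoding elements do not break tRNA adjacency
    core = [n for n in names if n not in ("OL", "D-loop")]
    doubled = core + core  # rotation-safe adjacency on the circle
    found = set()
    for label, members in _CLUSTERS.items():
        m = len(members)
        if any(tuple(doubled[i : i + m]) == members
               for i in range(len(core))):
            found.add(label)
    return found


def start_stop_codons(g: Mitogenome) -> list[CodonReport]:
    """Classify the start codon and the (possibly incomplete) stop codon of
    every protein-coding gene, in coding-strand orientation.

    The stop codon is the final ``length mod 3`` bases (3 when the length is
    a codon multiple), padded with ``-`` to 3 characters; for light-strand
    genes the majority-strand reading is reported alongside so both
    orientation conventions are inspectable.
    """
    elements = _ordered_elements(g)
    cds = [f for f in elements if f.type == "CDS"]
    if not cds:
        raise ValidationError(f"{g.accession}: no CDS features")
    reports = []
    for f in cds:
        seq = extract_gene_sequence(g, f)
        if len(seq) < 6:
            raise ValidationError(
                f"CDS {f.canonical_name!r} shorter than 6 bases"
            )
        tail = len(seq) % 3 or 3
        stop = seq[-tail:] + "-" * (3 - tail)
        majority_start = majority_stop = None
        if f.strand == "light":
            maj = (g.sequence[f.start:] + g.sequence[: f.end]
                   if f.wraps_origin else g.sequence[f.start : f.end])
            majority_start = maj[:3]
            maj_tail = len(maj) % 3 or 3
            majority_stop = maj[-maj_tail:] + "-" * (3 - maj_tail)
        reports.append(CodonReport(
            gene=f.canonical_name,
            strand=f.strand,
            start_codon=seq[:3],
            stop_codon=stop,
            stop_class="incomplete" if "-" in stop else "complete",
            downstream_same_strand_trna=_downstream_is_same_strand_trna(
                elements, f),
            majority_start=majority_start,
            majority_stop=majority_stop,
        ))
    return reports


def _downstream_is_same_strand_trna(elements: list[GeneFeature],
                                    f: GeneFeature) -> bool:
    """Is the next feature in the gene's coding direction a same-strand tRNA?"""
    i = elements.index(f)
    step = 1 if f.strand == "heavy" else -1
    nxt = elements[(i + step) % len(elements)]
    return nxt.type == "tRNA" and nxt.strand == f.strand


def spacers_and_overlaps(g: Mitogenome) -> list[SpacerOverlap]:
    """Signed gap between every adjacent feature pair around the circle.

    Positive lengths are intergenic spacers, negative lengths overlaps, zero
    abutting genes; the last feature wraps to the first.
    """
    elements = _ordered_elements(g)
    L = g.length
    out = []
    for i, f in enumerate(elements):
        nxt = elements[(i + 1) % len(elements)]
        end_on_circle = f.start + f.length(L)  # may exceed L for wrap features
        nxt_start = nxt.start + (L if i + 1 == len(elements) else 0)
        gap = nxt_start - end_on_circle
        out.append(SpacerOverlap(f.canonical_name, nxt.canonical_name, gap,
                                 (f.strand, nxt.strand)))
    return out


def spacer_summary(entries: list[SpacerOverlap]) -> dict:
    spacers = [e.length for e in entries if e.length > 0]
    overlaps = [-e.length for e in entries if e.length < 0]
    return {
        "n_spacers": len(spacers),
        "min_spacer": min(spacers) if spacers else None,
        "max_spacer": max(spacers) if spacers else None,
        "n_overlaps": len(overlaps),
        "min_overlap": min(overlaps) if overlaps else None,
        "max_overlap": max(overlaps) if overlaps else None,
    }


def gene_order_table(report: GeneOrderReport) -> pd.DataFrame:
    rows = []
    for i, (name, strand) in enumerate(report.observed):
        exp = CANONICAL_ORDER[i] if i < len(CANONICAL_ORDER) else None
        rows.append({
            "position": i,
            "observed": name,
            "observed_strand": strand,
            "expected": exp[0] if exp else None,
            "expected_strand": exp[1] if exp else None,
            "match": exp == (name, strand),
        })
    return pd.DataFrame(rows)


def codon_report_table(reports: list[CodonReport]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in reports])


def spacer_table(entries: list[SpacerOverlap]) -> pd.DataFrame:
    return pd.DataFrame([
        {"upstream": e.upstream, "downstream": e.downstream,
         "length": e.length,
         "kind": ("spacer" if e.length > 0
                  else "overlap" if e.length < 0 else "abutting"),
         "upstream_strand": e.strands[0], "downstream_strand": e.strands[1]}
        for e in entries
    ])
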