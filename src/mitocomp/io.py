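"""Reading, writing and in-memory modelling of annotated mitochondrial genomes.

The in-memory model is a :class:`Mitogenome`: the majority-strand (heavy,
sequenced) nucleotide sequence of one circular mtDNA molecule plus an ordered
list of :class:`GeneFeature` annotations.  Interior coordinates are 0-based
half-open; GenBank's 1-based inclusive convention is converted at the I/O
boundary only.  Light-strand genes are stored as their reverse complement on
the majority strand and are re-oriented on extraction.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .errors import ParseError, ValidationError

FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "D-loop", "OL", "other")

#: Specificity ranking used when GenBank records carry duplicate gene/CDS
#: annotations for the same span; the most specific type wins.
_TYPE_RANK = {"CDS": 0, "tRNA": 0, "rRNA": 0, "D-loop": 0, "OL": 0, "other": 1}

_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb",
)

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}
_AA1 = {v.lower(): v for v in _AA3.values()}


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC nucleotide alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneFeature:
    """One annotated element of a mitogenome.

    ``start``/``end`` are 0-based half-open majority-strand coordinates;
    a feature spanning the arbitrary sequence origin of the circular
    molecule has ``wraps_origin=True`` and ``end <= start``.
    """

    canonical_name: str
    type: str
    strand: str  # "heavy" | "light"
    start: int
    end: int
    wraps_origin: bool = False
    anticodon: str | None = None
    name_warning: bool = False

    def length(self, genome_length: int) -> int:
        if self.wraps_origin:
            return genome_length - self.start + self.end
        return self.end - self.start

    def validate(self, genome_length: int) -> None:
        if not (0 <= self.start < genome_length) or self.end > genome_length:
            raise ValidationError(
                f"feature {self.canonical_name!r}: span [{self.start}, {self.end}) "
                f"outside genome of length {genome_length}"
            )
        if not self.wraps_origin and self.end <= self.start:
            raise ValidationError(
                f"feature {self.canonical_name!r}: empty or inverted span "
                f"[{self.start}, {self.end}) without wraps_origin"
            )
        if self.strand not in ("heavy", "light"):
            raise ValidationError(
                f"feature {self.canonical_name!r}: unknown strand {self.strand!r}"
            )


@dataclass
class Mitogenome:
    """Majority-strand sequence and ordered annotations of one mtDNA record."""

    accession: str
    organism: str
    sequence: str
    topology: str = "circular"
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.features.sort(key=lambda f: (f.start, f.end))

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        if not self.sequence:
            raise ValidationError(f"{self.accession}: empty sequence")
        for f in self.features:
            f.validate(self.length)

    def features_of_type(self, *types: str) -> list[GeneFeature]:
        return [f for f in self.features if f.type in types]

    def get(self, canonical_name: str) -> GeneFeature | None:
        for f in self.features:
            if f.canonical_name == canonical_name:
                return f
        return None


# ---------------------------------------------------------------------------
# Gene-name normalization
# ---------------------------------------------------------------------------

_CDS_SYNONYMS = {
    "coi": "COI", "co1": "COI", "cox1": "COI", "coxi": "COI", "mtco1": "COI",
    "coii": "COII", "co2": "COII", "cox2": "COII", "coxii": "COII",
    "coiii": "COIII", "co3": "COIII", "cox3": "COIII", "coxiii": "COIII",
    "cytochromecoxidasesubuniti": "COI",
    "cytochromecoxidasesubunitii": "COII",
    "cytochromecoxidasesubunitiii": "COIII",
    "nd1": "ND1", "nad1": "ND1", "nd2": "ND2", "nad2": "ND2",
    "nd3": "ND3", "nad3": "ND3", "nd4": "ND4", "nad4": "ND4",
    "nd4l": "ND4L", "nad4l": "ND4L", "nd5": "ND5", "nad5": "ND5",
    "nd6": "ND6", "nad6": "ND6",
    "atp6": "ATPase6", "atpase6": "ATPase6", "atpsynthasef0subunit6": "ATPase6",
    "atp8": "ATPase8", "atpase8": "ATPase8", "atpsynthasef0subunit8": "ATPase8",
    "cob": "CYTB", "cytb": "CYTB", "cytochromeb": "CYTB", "mtcyb": "CYTB",
}

_RRNA_SYNONYMS = {
    "12s": "12S", "rrns": "12S", "srrna": "12S", "12srrna": "12S",
    "12sribosomalrna": "12S", "smallsubunitribosomalrna": "12S", "mtrnr1": "12S",
    "16s": "16S", "rrnl": "16S", "lrrna": "16S", "16srrna": "16S",
    "16sribosomalrna": "16S", "largesubunitribosomalrna": "16S", "mtrnr2": "16S",
}

_DLOOP_SYNONYMS = {"dloop", "controlregion", "dloopcontrolregion", "crregion"}
_OL_SYNONYMS = {
    "ol", "olr", "originoflstrandreplication", "lstrandorigin",
    "lightstrandreplicationorigin", "replicationoriginl",
}

#: Anticodon → disambiguated tRNA identity for the duplicated Leu/Ser genes.
_LEU_SER_BY_ANTICODON = {
    ("Leu", "TAA"): "tRNA-Leu(UUR)", ("Leu", "UAA"): "tRNA-Leu(UUR)",
    ("Leu", "TAG"): "tRNA-Leu(CUN)", ("Leu", "UAG"): "tRNA-Leu(CUN)",
    ("Ser", "TGA"): "tRNA-Ser(UCN)", ("Ser", "UGA"): "tRNA-Ser(UCN)",
    ("Ser", "GCT"): "tRNA-Ser(AGY)", ("Ser", "GCU"): "tRNA-Ser(AGY)",
}

_TRNA_CANON_RE = re.compile(r"^tRNA-([A-Z][a-z]{2})(\((UUR|CUN|UCN|AGY)\))?$")
_CODON_FAMILY_RE = re.compile(r"\((uur|cun|ucn|agy)\)", re.I)
_PAREN_ANTICODON_RE = re.compile(r"\(([acgtu]{3})\)", re.I)


def _squash(raw: str) -> str:
    return re.sub(r"[\s_\-./]+", "", raw).lower()


def normalize_gene_name(
    raw: str,
    feature_type: str,
    anticodon: str | None = None,
) -> tuple[str, bool]:
    """Map an annotation-dialect gene name to its canonical form.

    Returns ``(canonical_name, warning)`` where ``warning`` is True when the
    name could not be mapped and is passed through unchanged.  tRNA-Leu and
    tRNA-Ser are disambiguated by anticodon when one is available; otherwise
    the ambiguous short form (``tRNA-Leu``/``tRNA-Ser``) is returned and the
    caller resolves it by canonical order of appearance.
    """
    if not raw:
        raise ValidationError("empty gene name")
    raw = raw.strip()

    if feature_type == "D-loop" or _squash(raw) in _DLOOP_SYNONYMS:
        return "D-loop", False
    if feature_type == "OL" or _squash(raw) in _OL_SYNONYMS:
        return "OL", False

    if feature_type == "tRNA" or raw.lower().startswith(("trn", "trna")):
        m = _TRNA_CANON_RE.match(raw)
        if m and m.group(1) in _AA3.values():
            aa, fam = m.group(1), m.group(2)
            if aa in ("Leu", "Ser") and not fam and anticodon:
                ac = anticodon.upper()
                hit = _LEU_SER_BY_ANTICODON.get((aa, ac)) or _LEU_SER_BY_ANTICODON.get(
                    (aa, ac.replace("U", "T"))
                )
                if hit:
                    return hit, False
            return raw, False
        return _normalize_trna(raw, anticodon)

    squashed = _squash(raw)
    if feature_type in ("CDS", "other", "gene") or squashed in _CDS_SYNONYMS:
        hit = _CDS_SYNONYMS.get(squashed)
        if hit:
            return hit, False
    if feature_type in ("rRNA", "other", "gene") or squashed in _RRNA_SYNONYMS:
        hit = _RRNA_SYNONYMS.get(squashed)
        if hit:
            return hit, False

    return raw, True


def _normalize_trna(raw: str, anticodon: str | None) -> tuple[str, bool]:
    """Decode trnX / trnL(uaa) / 'tRNA Leu' style transfer-RNA names."""
    fam = _CODON_FAMILY_RE.search(raw)
    paren = _PAREN_ANTICODON_RE.search(raw)
    if paren and not fam and anticodon is None:
        anticodon = paren.group(1).upper()
    body = _CODON_FAMILY_RE.sub("", raw)
    body = _PAREN_ANTICODON_RE.sub("", body)
    body = re.sub(r"^t?rna[\s_\-]*", "", body, flags=re.I)
    body = re.sub(r"^trn[\s_\-]*", "", body, flags=re.I)
    body = body.strip(" -_")

    aa: str | None = None
    if len(body) == 1:
        aa = _AA3.get(body.upper())
    elif body.lower() in _AA1:
        aa = _AA1[body.lower()]
    if aa is None:
        return raw, True

    if fam:
        return f"tRNA-{aa}({fam.group(1).upper()})", False
    if aa in ("Leu", "Ser"):
        if anticodon:
            ac = anticodon.upper()
            hit = _LEU_SER_BY_ANTICODON.get((aa, ac)) or _LEU_SER_BY_ANTICODON.get(
                (aa, ac.replace("U", "T"))
            )
            if hit:
                return hit, False
        return f"tRNA-{aa}", False  # ambiguous; resolved by order of appearance
    return f"tRNA-{aa}", False


def resolve_ambiguous_leu_ser(features: list[GeneFeature]) -> None:
    """Assign the duplicated Leu/Ser identities by canonical order of appearance.

    In the typical vertebrate arrangement tRNA-Leu(UUR) (after 16S) precedes
    tRNA-Leu(CUN) (HSL cluster) and tRNA-Ser(UCN) (after COI) precedes
    tRNA-Ser(AGY) (HSL cluster); the first occurrence in genome order takes
    the earlier canonical identity when no anticodon disambiguates.
    """
    first = {"tRNA-Leu": "tRNA-Leu(UUR)", "tRNA-Ser": "tRNA-Ser(UCN)"}
    second = {"tRNA-Leu": "tRNA-Leu(CUN)", "tRNA-Ser": "tRNA-Ser(AGY)"}
    seen: dict[str, int] = {}
    for f in features:
        if f.canonical_name in ("tRNA-Leu", "tRNA-Ser"):
            n = seen.get(f.canonical_name, 0)
            f.canonical_name = (first if n == 0 else second)[f.canonical_name]
            seen[f.canonical_name.split("(")[0]] = n + 1


# ---------------------------------------------------------------------------
# Sequence extraction
# ---------------------------------------------------------------------------

def extract_gene_sequence(g: Mitogenome, f: GeneFeature) -> str:
    """Coding-strand sequence of one feature.

    Majority-strand slice for heavy-strand features, reverse complement for
    light-strand ones; wrap-around spans concatenate the tail and head slices
    before orientation.
    """
    f.validate(g.length)
    if f.wraps_origin:
        raw = g.sequence[f.start:] + g.sequence[: f.end]
    else:
        raw = g.sequence[f.start : f.end]
    return reverse_complement(raw) if f.strand == "light" else raw


def rotate_genome(g: Mitogenome, offset: int) -> Mitogenome:
    """Move the sequence origin of a circular genome to position ``offset``."""
    L = g.length
    offset %= L
    seq = g.sequence[offset:] + g.sequence[:offset]
    feats = []
    for f in g.features:
        flen = f.length(L)
        start = (f.start - offset) % L
        end = start + flen
        wraps = end > L
        feats.append(replace(f, start=start, end=end % L if wraps else end,
                             wraps_origin=wraps))
    return Mitogenome(g.accession, g.organism, seq, g.topology, feats)


# ---------------------------------------------------------------------------
# GenBank I/O
# ---------------------------------------------------------------------------

_GB_TYPE_IN = {
    "CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
    "D-loop": "D-loop", "D_loop": "D-loop", "rep_origin": "OL",
    "gene": "other", "misc_feature": "other",
}
_GB_TYPE_OUT = {
    "CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
    "D-loop": "D-loop", "OL": "rep_origin", "other": "misc_feature",
}

_ANTICODON_NOTE_RE = re.compile(r"anticodon[:=\s]+([A-Za-z]{3})")


def _feature_name(feat: SeqFeature) -> str:
    for key in ("gene", "product", "note", "standard_name"):
        vals = feat.qualifiers.get(key)
        if vals:
            return str(vals[0])
    return feat.type


def _feature_anticodon(feat: SeqFeature) -> str | None:
    for key in ("anticodon", "note"):
        for val in feat.qualifiers.get(key, []):
            m = _ANTICODON_NOTE_RE.search(str(val))
            if m:
                return m.group(1).upper().replace("U", "T")
            if key == "anticodon" and re.fullmatch(r"[ACGTUacgtu]{3}", str(val)):
                return str(val).upper().replace("U", "T")
    return None


def parse_genbank(path) -> Mitogenome:
    """Parse a GenBank flat file into a :class:`Mitogenome`.

    Coordinates are converted to 0-based half-open; ``join(...)`` locations
    spanning the origin become ``wraps_origin`` features; gene names are
    canonicalized via :func:`normalize_gene_name`; duplicate gene/CDS
    annotations over the same span collapse to the most specific type.
    """
    try:
        record = SeqIO.read(path, "genbank")
    except Exception as exc:  # noqa: BLE001 - normalize Biopython errors
        raise ParseError(f"cannot parse GenBank file {path}: {exc}") from exc
    seq = str(record.seq).upper()
    if not seq or set(seq) == {"N"} and len(seq) < 10:
        raise ParseError(f"{path}: record has no usable ORIGIN sequence")
    L = len(seq)
    topology = record.annotations.get("topology", "linear")

    feats: list[GeneFeature] = []
    for feat in record.features:
        if feat.type == "source":
            continue
        ftype = _GB_TYPE_IN.get(feat.type)
        if ftype is None:
            ftype = "other"
        start, end, wraps = _convert_location(feat, L)
        if start < 0 or end > L or start >= L:
            raise ValidationError(
                f"feature {_feature_name(feat)!r}: location outside sequence"
            )
        anticodon = _feature_anticodon(feat) if ftype == "tRNA" else None
        name, warn = normalize_gene_name(_feature_name(feat), ftype, anticodon)
        strand = "light" if feat.location.strand == -1 else "heavy"
        feats.append(GeneFeature(name, ftype, strand, start, end, wraps,
                                 anticodon, warn))

    resolve_ambiguous_leu_ser(feats)
    feats = _dedupe(feats)
    g = Mitogenome(record.id or record.name, record.annotations.get("organism", ""),
                   seq, topology, feats)
    g.validate()
    return g


def _convert_location(feat: SeqFeature, L: int) -> tuple[int, int, bool]:
    loc = feat.location
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        if (len(parts) == 2 and int(parts[1].end) == L and int(parts[0].start) == 0):
            return int(parts[1].start), int(parts[0].end), True
    return int(loc.start), int(loc.end), False


def _dedupe(feats: list[GeneFeature]) -> list[GeneFeature]:
    """Collapse duplicate annotations of one span, keeping the specific type."""
    best: dict[tuple, GeneFeature] = {}
    order: list[tuple] = []
    for f in feats:
        key = (f.canonical_name, f.start, f.end, f.wraps_origin)
        if key not in best:
            best[key] = f
            order.append(key)
        elif _TYPE_RANK[f.type] < _TYPE_RANK[best[key].type]:
            best[key] = f
    return [best[k] for k in order]


def write_genbank(g: Mitogenome, path) -> None:
    """Write a :class:`Mitogenome` as a GenBank flat file (round-trip safe)."""
    record = SeqRecord(Seq(g.sequence), id=g.accession, name=g.accession.split(".")[0],
                       description=f"{g.organism} mitochondrion, complete genome")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = g.topology
    record.annotations["organism"] = g.organism
    L = g.length
    record.features.append(SeqFeature(SimpleLocation(0, L, 1), type="source",
                                      qualifiers={"organism": [g.organism]}))
    for f in g.features:
        strand = -1 if f.strand == "light" else 1
        if f.wraps_origin:
            tail = SimpleLocation(f.start, L, strand)
            head = SimpleLocation(0, f.end, strand)
            parts = [tail, head] if strand == 1 else [head, tail]
            loc = CompoundLocation(parts)
        else:
            loc = SimpleLocation(f.start, f.end, strand)
        quals: dict[str, list[str]] = {"gene": [f.canonical_name]}
        if f.anticodon:
            quals["note"] = [f"anticodon:{f.anticodon}"]
        record.features.append(SeqFeature(loc, type=_GB_TYPE_OUT[f.type],
                                          qualifiers=quals))
    with open(path, "w") as fh:
        SeqIO.write(record, fh, "genbank")


# ---------------------------------------------------------------------------
# FASTA and feature-table export
# ---------------------------------------------------------------------------

def write_fasta(records: dict[str, str], path, wrap: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def read_fasta(path) -> dict[str, str]:
    out: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ParseError(f"{path}: no FASTA records found")
    return out


def feature_table(g: Mitogenome):
    """Tab-separated-ready table: name, type, strand, 1-based start/end, length."""
    import pandas as pd

    rows = [
        {
            "name": f.canonical_name,
            "type": f.type,
            "strand": f.strand,
            "start": f.start + 1,
            "end": f.end if not f.wraps_origin else f.end,  # 1-based inclusive end
            "length": f.length(g.length),
            "wraps_origin": f.wraps_origin,
        }
        for f in g.features
    ]
    return pd.DataFrame(rows)
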