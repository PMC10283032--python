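"""Synthetic annotated mitogenomes, mutated sequence pairs and quality reads.

The generator emulates the statistical structure of a teleost mitochondrial
genome: a ~16.4–16.6 kb circular molecule carrying the 37 canonical genes
plus control region in typical vertebrate order, AT-rich with a negative
GC-skew on the majority strand, codon-level protein-coding genes with an
A/C-ending third-position bias, ATG starts (GTG for COI), a mix of complete
and incomplete stop codons before same-strand tRNAs, small intergenic
spacers, and single-end reads whose Phred quality decays toward the 3' end.

All randomness flows from one root seed through per-component substreams
(genome / mutation / reads), so adding a stage never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .architecture import CANONICAL_ORDER
from .errors import ValidationError
from .io import GeneFeature, Mitogenome, reverse_complement
from .trim import QualityRead

# ---------------------------------------------------------------------------
# Fixed biological constants used by the generator
# ---------------------------------------------------------------------------

#: Body-codon count (excluding start and stop) and stop string per CDS; the
#: resulting gene lengths sit at typical teleost values, and COII/ND3/CYTB get
#: the incomplete T-- stop, ND2 TA-, ND4 the rare AGA, as commonly annotated.
CDS_PLAN: dict[str, tuple[int, str, str]] = {
    # gene: (body_codons, start_codon, stop_string)
    "ND1": (323, "ATG", "TAA"),
    "ND2": (347, "ATG", "TA"),
    "COI": (515, "GTG", "TAA"),
    "COII": (229, "ATG", "T"),
    "ATPase8": (54, "ATG", "TAA"),
    "ATPase6": (226, "ATG", "TAA"),
    "COIII": (260, "ATG", "TA"),
    "ND3": (115, "ATG", "T"),
    "ND4L": (97, "ATG", "TAA"),
    "ND4": (458, "ATG", "AGA"),
    "ND5": (611, "ATG", "TAA"),
    "ND6": (172, "ATG", "TAA"),
    "CYTB": (379, "ATG", "T"),
}

#: Standard vertebrate mitochondrial tRNA anticodons (DNA alphabet).
TRNA_ANTICODONS: dict[str, str] = {
    "tRNA-Phe": "GAA", "tRNA-Val": "TAC", "tRNA-Leu(UUR)": "TAA",
    "tRNA-Ile": "GAT", "tRNA-Gln": "TTG", "tRNA-Met": "CAT",
    "tRNA-Trp": "TCA", "tRNA-Ala": "TGC", "tRNA-Asn": "GTT",
    "tRNA-Cys": "GCA", "tRNA-Tyr": "GTA", "tRNA-Ser(UCN)": "TGA",
    "tRNA-Asp": "GTC", "tRNA-Lys": "TTT", "tRNA-Gly": "TCC",
    "tRNA-Arg": "TCG", "tRNA-His": "GTG", "tRNA-Ser(AGY)": "GCT",
    "tRNA-Leu(CUN)": "TAG", "tRNA-Glu": "TTC", "tRNA-Thr": "TGT",
    "tRNA-Pro": "TGG",
}

#: Amino-acid sampling frequencies for CDS bodies, shaped like a fish
#: mitochondrial proteome (Leu-rich, Cys-poor); normalized at use.
AA_FREQUENCIES: dict[str, float] = {
    "L": 0.170, "A": 0.092, "T": 0.085, "S": 0.068, "I": 0.067,
    "G": 0.048, "F": 0.059, "V": 0.058, "P": 0.055, "M": 0.055,
    "N": 0.037, "Y": 0.032, "W": 0.022, "K": 0.025, "H": 0.025,
    "Q": 0.024, "E": 0.024, "R": 0.018, "D": 0.019, "C": 0.011,
}

#: Third-position weights inducing the A/C-ending codon bias of fish
#: mitogenomes (A-ending favoured, G-ending penalized).
THIRD_POSITION_WEIGHTS: dict[str, float] = {"A": 0.36, "C": 0.33,
                                            "T": 0.16, "G": 0.15}


@dataclass
class SynthSpec:
    """Tunable parameters of the synthetic mitogenome/read generator.

    Composition defaults target the values typical of snake-mackerel-like
    mitogenomes: whole-genome A+T around 54%, weakly positive AT-skew and
    clearly negative GC-skew on the majority strand, and a markedly AT-rich
    control region.
    """

    seed: int = 0
    gene_order: tuple[tuple[str, str], ...] = CANONICAL_ORDER
    genome_length_target: int | None = None  # None: natural (~16.4-16.6 kb)
    at_percent: float = 54.0
    at_skew: float = 0.04
    gc_skew: float = -0.27
    dloop_at_percent: float = 66.0
    dloop_at_skew: float = 0.03
    dloop_gc_skew: float = -0.20
    dloop_length: int | None = None  # None: drawn from [603, 862]
    codon_model: bool = True  # codon-level CDS generation (RSCU structure)
    cds_stop_overrides: dict[str, str] = field(default_factory=dict)
    spacers: dict[str, int] = field(default_factory=dict)  # upstream gene -> bp
    max_random_spacer: int = 3
    # mutation
    p_ts: float = 0.010
    p_tv: float = 0.005
    # reads
    n_reads: int = 2000
    read_len_mean: float = 374.0
    read_len_sd: float = 80.0
    read_len_min: int = 50
    qv_start: float = 36.0
    qv_decay: float = 0.05  # Phred units lost per base toward the 3' end
    qv_noise_sd: float = 5.0


def _substream(seed: int, index: int) -> np.random.Generator:
    """Independent RNG substream ``index`` derived from the root seed."""
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[index])


def base_probabilities(at_percent: float, at_skew: float,
                       gc_skew: float) -> dict[str, float]:
    """Per-base sampling probabilities realizing the target A+T% and skews."""
    at = at_percent / 100.0
    if not (0.0 <= at <= 1.0 and -1.0 <= at_skew <= 1.0 and -1.0 <= gc_skew <= 1.0):
        raise ValidationError("composition targets out of range")
    return {
        "A": at * (1.0 + at_skew) / 2.0,
        "T": at * (1.0 - at_skew) / 2.0,
        "G": (1.0 - at) * (1.0 + gc_skew) / 2.0,
        "C": (1.0 - at) * (1.0 - gc_skew) / 2.0,
    }


def _random_seq(rng: np.random.Generator, length: int,
                probs: dict[str, float]) -> str:
    bases = np.array(list("ATGC"))
    p = np.array([probs[b] for b in "ATGC"])
    return "".join(rng.choice(bases, size=length, p=p / p.sum()))


def _sample_codons(rng: np.random.Generator, n: int) -> list[str]:
    """Sample amino acids from the proteome profile, then a synonymous codon
    weighted by third-position bias (vertebrate mitochondrial code)."""
    from .codon import FAMILIES

    aas = list(AA_FREQUENCIES)
    p = np.array([AA_FREQUENCIES[a] for a in aas])
    chosen = rng.choice(len(aas), size=n, p=p / p.sum())
    out = []
    for i in chosen:
        codons = FAMILIES[aas[i]]
        w = np.array([THIRD_POSITION_WEIGHTS[c[2]] for c in codons])
        out.append(codons[rng.choice(len(codons), p=w / w.sum())])
    return out


def _cds_sequence(rng: np.random.Generator, gene: str, spec: SynthSpec,
                  probs: dict[str, float]) -> str:
    body, start, stop = CDS_PLAN[gene]
    stop = spec.cds_stop_overrides.get(gene, stop)
    if spec.codon_model:
        middle = "".join(_sample_codons(rng, body))
    else:
        middle = _random_seq(rng, body * 3, probs)
    return start + middle + stop


def synth_mitogenome(spec: SynthSpec) -> Mitogenome:
    """Generate one annotated circular mitogenome; deterministic given seed."""
    rng = _substream(spec.seed, 0)
    probs = base_probabilities(spec.at_percent, spec.at_skew, spec.gc_skew)
    dloop_probs = base_probabilities(spec.dloop_at_percent, spec.dloop_at_skew,
                                     spec.dloop_gc_skew)

    chunks: list[str] = []
    features: list[GeneFeature] = []
    pos = 0
    for name, strand in spec.gene_order:
        if name in CDS_PLAN:
            ftype, coding = "CDS", _cds_sequence(rng, name, spec, probs)
        elif name in TRNA_ANTICODONS:
            ftype = "tRNA"
            coding = _random_seq(rng, int(rng.integers(65, 77)), probs)
        elif name in ("12S", "16S"):
            ftype = "rRNA"
            coding = _random_seq(rng, 950 if name == "12S" else 1700, probs)
        elif name == "OL":
            ftype, coding = "OL", _random_seq(rng, 35, probs)
        elif name == "D-loop":
            ftype = "D-loop"
            length = (spec.dloop_length if spec.dloop_length is not None
                      else int(rng.integers(603, 863)))
            coding = _random_seq(rng, length, dloop_probs)
        else:
            raise ValidationError(f"unknown element in gene order: {name!r}")

        placed = reverse_complement(coding) if strand == "light" else coding
        start = pos
        chunks.append(placed)
        pos += len(placed)
        features.append(GeneFeature(
            name, ftype, strand, start, pos,
            anticodon=TRNA_ANTICODONS.get(name),
        ))
        spacer = spec.spacers.get(name)
        if spacer is None:
            spacer = int(rng.integers(0, spec.max_random_spacer + 1))
        if spacer < 0:
            raise ValidationError("negative spacers are not constructible")
        if spacer:
            chunks.append(_random_seq(rng, spacer, probs))
            pos += spacer

    if spec.genome_length_target is not None:
        if pos > spec.genome_length_target:
            raise ValidationError(
                f"genes span {pos} bases, exceeding the "
                f"{spec.genome_length_target}-base genome target"
            )
        if pos < spec.genome_length_target:
            chunks.append(_random_seq(rng, spec.genome_length_target - pos,
                                      probs))
            pos = spec.genome_length_target

    g = Mitogenome(
        accession=f"SYN{spec.seed:07d}",
        organism="synthetic teleost-like mitogenome",
        sequence="".join(chunks),
        topology="circular",
        features=features,
    )
    g.validate()
    return g


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_DECODE = np.array(list("ACGT"))


def mutate(seq: str, p_ts: float, p_tv: float, seed: int) -> str:
    """Mutate each site independently: transition with probability ``p_ts``,
    transversion (uniform over the two options) with probability ``p_tv``.

    Ambiguous bases are left untouched.  Deterministic given seed.
    """
    if min(p_ts, p_tv) < 0 or p_ts + p_tv > 1:
        raise ValidationError(
            f"need p_ts, p_tv >= 0 and p_ts + p_tv <= 1, got {p_ts}, {p_tv}"
        )
    rng = _substream(seed, 1)
    codes = np.array([_CODE.get(b, -1) for b in seq.upper()], dtype=np.int64)
    valid = codes >= 0
    u = rng.random(len(codes))
    bit = rng.integers(0, 2, len(codes))
    ts_mask = (u < p_ts) & valid
    tv_mask = (u >= p_ts) & (u < p_ts + p_tv) & valid

    out = codes.copy()
    out[ts_mask] = codes[ts_mask] ^ 2  # A<->G (0,2), C<->T (1,3)
    purine = (codes % 2) == 0  # A, G
    tv_pur = tv_mask & purine  # purine -> C or T: 1 or 3
    tv_pyr = tv_mask & ~purine  # pyrimidine -> A or G: 0 or 2
    out[tv_pur] = 1 + 2 * bit[tv_pur]
    out[tv_pyr] = 2 * bit[tv_pyr]

    result = np.array(list(seq.upper()))
    result[valid] = _DECODE[out[valid]]
    return "".join(result)


def mutated_pair(spec: SynthSpec) -> tuple[str, str]:
    """A 16 kb ancestral sequence and a derived copy mutated at the
    configured transition/transversion pressures (distance-recovery input)."""
    rng = _substream(spec.seed, 0)
    probs = base_probabilities(spec.at_percent, spec.at_skew, spec.gc_skew)
    ancestor = _random_seq(rng, 16000, probs)
    return ancestor, mutate(ancestor, spec.p_ts, spec.p_tv, spec.seed)


def synth_reads(g: Mitogenome, spec: SynthSpec) -> list[QualityRead]:
    """Sample single-end reads uniformly from the circular genome (both
    strands) with 3'-decaying Phred qualities; deterministic given seed."""
    if g.length == 0:
        raise ValidationError("cannot sample reads from an empty genome")
    rng = _substream(spec.seed, 2)
    doubled = g.sequence + g.sequence
    reads = []
    lengths = rng.normal(spec.read_len_mean, spec.read_len_sd, spec.n_reads)
    lengths = np.clip(np.rint(lengths), spec.read_len_min, g.length).astype(int)
    starts = rng.integers(0, g.length, spec.n_reads)
    strands = rng.integers(0, 2, spec.n_reads)
    for i in range(spec.n_reads):
        n = int(lengths[i])
        seq = doubled[starts[i] : starts[i] + n]
        if strands[i]:
            seq = reverse_complement(seq)
        qv_mean = spec.qv_start - spec.qv_decay * np.arange(n)
        qv = np.rint(qv_mean + rng.normal(0.0, spec.qv_noise_sd, n))
        qv = np.clip(qv, 0, 40).astype(int)
        reads.append(QualityRead(f"synthread_{i:06d}", seq, qv.tolist()))
    return reads


def write_fastq(reads: list[QualityRead], path, qv_offset: int = 33) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + qv_offset) for q in r.qv)
            fh.write(f"@{r.id}\n{r.bases}\n+\n{qual}\n")


def expected_divergence(p_ts: float, p_tv: float) -> float:
    """Analytic K2P expectation for a pair separated by one mutation round
    with per-site transition probability p_ts and transversion p_tv."""
    from .distances import k2p

    return k2p(p_ts, p_tv)
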