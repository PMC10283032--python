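"""Base counting, skew formulas, partitions, codon positions, per-gene stats."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocomp.composition import (
    BaseCounts,
    codon_position_composition,
    composition_record,
    count_bases,
    partition_stats,
    per_gene_profile,
    skews,
)
from mitocomp.errors import ValidationError
from mitocomp.io import GeneFeature, Mitogenome, reverse_complement
from mitocomp.synth import SynthSpec, base_probabilities, synth_mitogenome


@pytest.mark.parametrize(
    "seq, expected",
    [
        ("ACGT", BaseCounts(1, 1, 1, 1, 0)),
        ("AANN", BaseCounts(a=2, ambiguous=2)),
        ("", BaseCounts()),
        ("acgu", BaseCounts(1, 1, 1, 1, 0)),  # case-insensitive, U as T
    ],
)
def test_count_bases(seq, expected):
    assert count_bases(seq) == expected


def test_count_bases_rejects_non_iupac():
    with pytest.raises(ValidationError):
        count_bases("ACGX")


@pytest.mark.parametrize(
    "counts, at, gc",
    [
        (BaseCounts(a=5, t=5), 0.0, None),
        (BaseCounts(a=6, t=4), 0.2, None),
        (BaseCounts(g=3, c=1), None, 0.5),
        (BaseCounts(), None, None),
    ],
)
def test_skew_formula(counts, at, gc):
    at_skew, gc_skew = skews(counts)
    assert at_skew == pytest.approx(at) if at is not None else at_skew is None
    assert gc_skew == pytest.approx(gc) if gc is not None else gc_skew is None


@given(st.text(alphabet="ACGTN", min_size=0, max_size=500))
@settings(max_examples=300, deadline=None)
def test_skews_match_character_scan_oracle(seq):
    """Computed skews equal a brute-force per-character implementation."""
    a = sum(1 for ch in seq if ch == "A")
    t = sum(1 for ch in seq if ch == "T")
    g = sum(1 for ch in seq if ch == "G")
    c = sum(1 for ch in seq if ch == "C")
    at_skew, gc_skew = skews(count_bases(seq))
    assert at_skew == (None if a + t == 0 else pytest.approx((a - t) / (a + t)))
    assert gc_skew == (None if g + c == 0 else pytest.approx((g - c) / (g + c)))


@given(st.text(alphabet="ACGT", min_size=1, max_size=500))
@settings(max_examples=200, deadline=None)
def test_skews_antisymmetric_under_complement(seq):
    comp_seq = reverse_complement(seq)
    at1, gc1 = skews(count_bases(seq))
    at2, gc2 = skews(count_bases(comp_seq))
    assert (at2 is None) == (at1 is None)
    assert (gc2 is None) == (gc1 is None)
    if at1 is not None:
        assert at2 == pytest.approx(-at1)
    if gc1 is not None:
        assert gc2 == pytest.approx(-gc1)


def test_at_percent_and_percent_sum():
    rec = composition_record("r", "AATTGCGCGN")
    assert rec.at_percent == pytest.approx(100 * 4 / 9)
    assert sum(rec.base_percents.values()) == pytest.approx(100.0, abs=0.05)


def test_partition_stats_tiling_conservation(canonical_genome):
    """Partition + spacer base counts reconstruct the whole-genome counts."""
    recs = {r.region_label: r for r in partition_stats(canonical_genome)}
    assert set(recs) == {"Mito", "PCGs", "rRNAs", "tRNAs", "D-loop"}
    g = canonical_genome
    covered = sum(r.counts.total for label, r in recs.items() if label != "Mito")
    ol = [f for f in g.features if f.type == "OL"]
    gene_span = sum(f.length(g.length) for f in g.features if f.type != "other")
    spacer_total = g.length - gene_span
    assert covered + spacer_total + sum(f.length(g.length) for f in ol) == \
        recs["Mito"].counts.total == g.length


def test_missing_partition_warns_not_raises():
    g = Mitogenome(
        "X", "t", "ATGAAATAAATGCCCTAA",
        features=[GeneFeature("ND1", "CDS", "heavy", 0, 9),
                  GeneFeature("ND2", "CDS", "heavy", 9, 18)],
    )
    with pytest.warns(UserWarning, match="tRNAs"):
        recs = partition_stats(g)
    assert {r.region_label for r in recs} == {"Mito", "PCGs"}


def test_equal_base_probability_genome_has_near_zero_skews():
    """With symmetric base sampling, both skews stay within 3 SE of zero."""
    spec = SynthSpec(seed=11, at_percent=50.0, at_skew=0.0, gc_skew=0.0,
                     codon_model=False)
    g = synth_mitogenome(spec)
    recs = {r.region_label: r for r in partition_stats(g)}
    mito = recs["Mito"]
    n_at = mito.counts.a + mito.counts.t
    n_gc = mito.counts.g + mito.counts.c
    assert abs(mito.at_skew) <= 3 / math.sqrt(n_at)
    assert abs(mito.gc_skew) <= 3 / math.sqrt(n_gc)


def test_codon_position_enumerated_example():
    cpc = codon_position_composition(["ATGTAA"])
    assert cpc.positions["1"] == {"T": 50.0, "C": 0.0, "A": 50.0, "G": 0.0}
    assert cpc.positions["2"] == {"T": 50.0, "C": 0.0, "A": 50.0, "G": 0.0}
    assert cpc.positions["3"] == {"T": 0.0, "C": 0.0, "A": 50.0, "G": 50.0}


def test_codon_position_truncates_incomplete_terminal_codon():
    cpc = codon_position_composition(["ATGTAAC"])  # 7th base dropped
    assert cpc.counts["pooled"].total == 6


def test_codon_position_rejects_empty():
    with pytest.raises(ValidationError):
        codon_position_composition([])


def test_codon_position_anti_g_bias_at_second_position(genome_set):
    """Synthetic coding genes show the second-position G depletion typical
    of mitochondrial proteomes."""
    from mitocomp.io import extract_gene_sequence

    for g in genome_set:
        cds = [extract_gene_sequence(g, f) for f in g.features_of_type("CDS")]
        cpc = codon_position_composition(cds)
        g2 = cpc.positions["2"]["G"]
        assert g2 < cpc.positions["1"]["G"]
        assert g2 < cpc.positions["3"]["G"]


def test_per_gene_profile_shape_and_ranges(canonical_genome):
    df = per_gene_profile(canonical_genome)
    assert len(df) == 39  # 37 genes + D-loop + OL
    assert df["at_skew"].between(-1, 1).all()
    assert df["gc_skew"].between(-1, 1).all()
    assert list(df["gene"])[0] == canonical_genome.features[0].canonical_name


def test_per_gene_profile_pure_at_gene():
    g = Mitogenome("X", "t", "AATTAATTAATT",
                   features=[GeneFeature("ND1", "CDS", "heavy", 0, 12)])
    row = per_gene_profile(g).iloc[0]
    assert row["at_percent"] == pytest.approx(100.0)
    assert row["at_skew"] == pytest.approx(0.0)


def test_nd6_gc_skew_sign_flips_on_majority_strand(genome_set):
    """Light-strand ND6 shows positive majority-strand GC-skew while the
    heavy-strand protein genes stay negative (coding-strand profile is
    negative for all)."""
    from mitocomp.composition import _majority_slice

    for g in genome_set:
        df = per_gene_profile(g)  # coding-strand convention
        pcg = df[df["type"] == "CDS"]
        assert (pcg["gc_skew"] < 0).all()
        nd6 = g.get("ND6")
        maj = composition_record("ND6maj", _majority_slice(g, nd6))
        assert maj.gc_skew > 0


def test_base_probabilities_realize_targets():
    p = base_probabilities(54.0, 0.05, -0.27)
    assert sum(p.values()) == pytest.approx(1.0)
    assert p["A"] + p["T"] == pytest.approx(0.54)
    assert (p["A"] - p["T"]) / (p["A"] + p["T"]) == pytest.approx(0.05)
    assert (p["G"] - p["C"]) / (p["G"] + p["C"]) == pytest.approx(-0.27)
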