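"""Codon counting, RSCU normalization and bias classes, amino-acid usage."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocomp.codon import (
    ALL_CODONS,
    CODON_TO_AA,
    FAMILIES,
    STOP_CODONS,
    CodonUsageTable,
    amino_acid_counts,
    classify_rscu,
    codon_counts,
    rscu,
    rscu_table,
)
from mitocomp.errors import ValidationError


def test_vertebrate_mito_code_structure():
    """AGA/AGG are stops, ATA is Met, TGA is Trp; families partition 64."""
    assert STOP_CODONS == {"TAA", "TAG", "AGA", "AGG"}
    assert CODON_TO_AA["ATA"] == "M"
    assert CODON_TO_AA["TGA"] == "W"
    assert sorted(FAMILIES["L"]) == ["CTA", "CTC", "CTG", "CTT", "TTA", "TTG"]
    assert sorted(FAMILIES["S"]) == ["AGC", "AGT", "TCA", "TCC", "TCG", "TCT"]
    assert sum(len(v) for v in FAMILIES.values()) == 64


def test_codon_counts_enumeration():
    t = codon_counts(["ATGCTATAA"], include_stops=True)
    assert t.counts["ATG"] == t.counts["CTA"] == t.counts["TAA"] == 1
    assert t.total_codons == 3


def test_codon_counts_drops_trailing_bases():
    t = codon_counts(["ATGCTAT"])
    assert t.total_codons == 2
    assert t.dropped_trailing == 1


def test_codon_counts_exclude_stops():
    t = codon_counts(["ATGTAAAGA"], include_stops=False)
    assert t.total_codons == 1
    assert t.counts["TAA"] == 0 and t.counts["AGA"] == 0


def test_codon_counts_drops_ambiguous_codons():
    t = codon_counts(["ATGNNNCTA"])
    assert t.total_codons == 2
    assert t.dropped_ambiguous == 1


def test_codon_counts_rejects_empty():
    with pytest.raises(ValidationError):
        codon_counts([])


def test_codon_count_conservation_brute_force(genome_set):
    """total + ambiguous-dropped codons equals floor(len/3) summed over CDS."""
    from mitocomp.io import extract_gene_sequence

    for g in genome_set:
        cds = [extract_gene_sequence(g, f) for f in g.features_of_type("CDS")]
        t = codon_counts(cds, include_stops=True)
        assert t.total_codons + t.dropped_ambiguous == sum(
            len(s) // 3 for s in cds)
        assert t.dropped_trailing == sum(len(s) % 3 for s in cds)


def test_rscu_phe_family_forced_by_formula():
    counts = {c: 0 for c in ALL_CODONS}
    counts.update({"TTT": 3, "TTC": 1})
    prof = rscu(CodonUsageTable(counts, 4, True))
    assert prof.rscu["TTT"] == pytest.approx(1.5)
    assert prof.rscu["TTC"] == pytest.approx(0.5)


def test_rscu_equal_counts_give_unity():
    counts = {c: 5 for c in ALL_CODONS}
    prof = rscu(CodonUsageTable(counts, 64 * 5, True))
    assert all(v == pytest.approx(1.0) for v in prof.rscu.values())
    assert all(c == "unbiased" for c in prof.bias_class.values())


@pytest.mark.parametrize(
    "value, expected",
    [
        (1.7, "overrepresented"),
        (1.61, "overrepresented"),
        (1.6, "positive"),
        (1.1, "positive"),
        (1.0, "unbiased"),
        (0.9, "negative"),
        (0.6, "negative"),
        (0.55, "underrepresented"),
    ],
)
def test_bias_class_thresholds(value, expected):
    assert classify_rscu(value) == expected


def test_unused_family_class():
    counts = {c: 0 for c in ALL_CODONS}
    counts["ATG"] = 3  # Met used, everything else empty
    prof = rscu(CodonUsageTable(counts, 3, True))
    assert prof.bias_class["TTT"] == "unused-family"
    assert prof.rscu["TTT"] == 0.0


@st.composite
def random_usage_tables(draw):
    counts = {c: 0 for c in ALL_CODONS}
    for c in draw(st.sets(st.sampled_from(ALL_CODONS), min_size=1, max_size=40)):
        counts[c] = draw(st.integers(min_value=0, max_value=500))
    return CodonUsageTable(counts, sum(counts.values()), True)


@given(random_usage_tables())
@settings(max_examples=200, deadline=None)
def test_rscu_family_sums_equal_family_size(table):
    """Within every used family the RSCU values sum to n_i."""
    prof = rscu(table)
    for fam, codons in table.families.items():
        total = sum(table.counts[c] for c in codons)
        if total:
            assert sum(prof.rscu[c] for c in codons) == pytest.approx(len(codons))


@given(random_usage_tables(), st.integers(min_value=2, max_value=9))
@settings(max_examples=100, deadline=None)
def test_rscu_scale_invariance(table, k):
    scaled = CodonUsageTable({c: n * k for c, n in table.counts.items()},
                             table.total_codons * k, True)
    base = rscu(table).rscu
    for codon, value in rscu(scaled).rscu.items():
        assert value == pytest.approx(base[codon])


def test_amino_acid_counts_pools_leu_families():
    counts = {c: 0 for c in ALL_CODONS}
    counts.update({"ATG": 2, "CTA": 2, "TTA": 1})
    res = amino_acid_counts(CodonUsageTable(counts, 5, True))
    assert res["counts"]["Met"] == 2
    assert res["counts"]["Leu"] == 3  # CUN + UUR pooled
    assert res["most_frequent"] == "Leu"
    assert not res["tie"]


def test_amino_acid_counts_degenerate_empty():
    counts = {c: 0 for c in ALL_CODONS}
    counts["TAA"] = 7  # stop-only usage: no ranking
    res = amino_acid_counts(CodonUsageTable(counts, 7, True))
    assert res["most_frequent"] is None


def test_rscu_table_long_format(genome_set):
    from mitocomp.io import extract_gene_sequence

    cds = [extract_gene_sequence(g, f)
           for g in genome_set for f in g.features_of_type("CDS")]
    df = rscu_table(codon_counts(cds, include_stops=True))
    assert len(df) == 64
    assert set(df.columns) == {"codon", "amino_acid", "count", "rscu",
                               "bias_class"}
    # A-ending codons are favoured over G-ending ones in synthetic PCGs
    a_mean = df[df["codon"].str.endswith("A")]["rscu"].mean()
    g_mean = df[df["codon"].str.endswith("G")]["rscu"].mean()
    assert a_mean > 1.0 > g_mean


def test_synthetic_panel_aa_usage_extremes(genome_set):
    """Leu is the most and Cys the least frequent amino acid in the panel."""
    from mitocomp.io import extract_gene_sequence

    for g in genome_set:
        cds = [extract_gene_sequence(g, f) for f in g.features_of_type("CDS")]
        res = amino_acid_counts(codon_counts(cds, include_stops=True))
        assert res["most_frequent"] == "Leu"
        assert res["least_frequent"] == "Cys"
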