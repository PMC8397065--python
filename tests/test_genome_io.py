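"""Genome I/O: name normalization, coordinate handling, format round trips."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_toy_genome
from mitochar.errors import CoordinateError, ParseError
from mitochar.genome_io import (
    CANONICAL_GENES,
    AnnotatedMitogenome,
    GeneFeature,
    extract_feature_sequence,
    normalize_gene_name,
    read_fasta,
    read_genbank,
    reverse_complement,
    rotate,
    write_fasta,
    write_feature_table,
    write_genbank,
)


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("COI", "cox1"),
        ("cox1", "cox1"),
        ("ND4L", "nad4L"),
        ("NADH5", "nad5"),
        ("tRNA-Leu(UUR)", "trnL2"),
        ("trnL-cun", "trnL1"),
        ("tRNA-Ser(AGN)", "trnS1"),
        ("tRNA-Ser (UCN)", "trnS2"),
        ("16S ribosomal RNA", "rrnL"),
        ("l-rRNA", "rrnL"),
        ("12S", "rrnS"),
        ("D-loop", "AT-rich"),
        ("control region", "AT-rich"),
        ("CYTB", "Cytb"),
        ("tRNA-Met", "trnM"),
        ("tRNA-Leu", "unknown"),  # ambiguous without anticodon family
        ("hypothetical ORF", "unknown"),
        ("", "unknown"),
    ],
)
def test_normalize_gene_name_dialects(raw, expected):
    assert normalize_gene_name(raw) == expected


@given(st.text(min_size=0, max_size=30))
@settings(max_examples=200, deadline=None)
def test_normalize_is_idempotent_and_total(raw):
    once = normalize_gene_name(raw)
    assert normalize_gene_name(once) == once  # canonical names are fixed points


def test_all_canonical_names_are_fixed_points():
    for name in CANONICAL_GENES + ("AT-rich",):
        assert normalize_gene_name(name) == name


class TestExtractFeatureSequence:
    def test_majority_strand_slice(self):
        g = make_toy_genome("AACGTT", [("cox1", "PCG", 0, 6, "J")])
        f = GeneFeature("trnM", "tRNA", 2, 5, "J")
        assert extract_feature_sequence(g, f) == "CGT"

    def test_minority_strand_is_reverse_complement(self):
        g = make_toy_genome("AACGTT", [("cox1", "PCG", 0, 6, "J")])
        f = GeneFeature("trnM", "tRNA", 2, 5, "N")
        assert extract_feature_sequence(g, f) == "ACG"

    def test_wraparound_uses_doubled_string(self):
        g = make_toy_genome("AACGTT", [("cox1", "PCG", 0, 6, "J")])
        f = GeneFeature("trnM", "tRNA", 5, 8, "J")
        doubled = ("AACGTT" * 2)[5:8]
        assert extract_feature_sequence(g, f) == doubled == "TAA"

    def test_n_strand_always_revcomp_of_j_strand(self):
        rng = random.Random(5)
        seq = "".join(rng.choice("ACGT") for _ in range(300))
        g = make_toy_genome(seq, [("cox1", "PCG", 0, 10, "J")])
        for _ in range(50):
            s = rng.randrange(300)
            e = s + rng.randrange(1, 300)
            j = extract_feature_sequence(g, GeneFeature("trnM", "tRNA", s, e, "J"))
            n = extract_feature_sequence(g, GeneFeature("trnM", "tRNA", s, e, "N"))
            assert n == reverse_complement(j)

    def test_feature_longer_than_genome_rejected(self):
        g = make_toy_genome("AACGTT", [("cox1", "PCG", 0, 6, "J")])
        with pytest.raises(CoordinateError):
            extract_feature_sequence(g, GeneFeature("trnM", "tRNA", 2, 10, "J"))


class TestValidation:
    def test_ambiguity_codes_rejected_n_allowed(self):
        make_toy_genome("ACGTN", [("cox1", "PCG", 0, 5, "J")])  # N fine
        with pytest.raises(ParseError):
            make_toy_genome("ACGTR", [("cox1", "PCG", 0, 5, "J")])

    def test_feature_start_outside_genome_rejected(self):
        with pytest.raises(CoordinateError):
            make_toy_genome("ACGT", [("cox1", "PCG", 7, 9, "J")])

    def test_two_control_regions_rejected(self):
        with pytest.raises(CoordinateError):
            make_toy_genome(
                "ACGTACGT",
                [("AT-rich", "control-region", 0, 2, "J"), ("AT-rich", "control-region", 4, 6, "J")],
            )


class TestRoundTrips:
    def test_genbank_round_trip_exact(self, tmp_path, default_genome):
        genome, _ = default_genome
        path = tmp_path / "g.gb"
        write_genbank(genome, path)
        back = read_genbank(path)
        assert back.sequence == genome.sequence
        assert len(back.features) == len(genome.features)
        for a, b in zip(genome.features, back.features):
            assert (a.canonical_name, a.start, a.end, a.strand) == (b.canonical_name, b.start, b.end, b.strand)

    def test_genbank_wraparound_feature_round_trip(self, tmp_path):
        seq = "ACGTACGTACGTACGTACGT"
        g = make_toy_genome(seq, [("trnM", "tRNA", 2, 6, "J"), ("rrnS", "rRNA", 16, 23, "N")])
        path = tmp_path / "wrap.gb"
        write_genbank(g, path)
        back = read_genbank(path)
        wrap = back.get("rrnS")
        assert (wrap.start, wrap.end, wrap.strand) == (16, 23, "N")
        assert extract_feature_sequence(back, wrap) == extract_feature_sequence(g, g.get("rrnS"))

    def test_fasta_sidecar_round_trip(self, tmp_path, default_genome):
        genome, _ = default_genome
        fa, tsv = tmp_path / "g.fasta", tmp_path / "g.tsv"
        write_fasta(genome, fa)
        write_feature_table(genome, tsv)
        back = read_fasta(fa, tsv)
        assert back.sequence == genome.sequence
        assert [(f.canonical_name, f.start, f.end, f.strand) for f in back.features] == [
            (f.canonical_name, f.start, f.end, f.strand) for f in genome.features
        ]

    def test_minimal_cds_coordinates_are_one_based_inclusive(self, tmp_path):
        gb = tmp_path / "m.gb"
        seq = "ATG" + "AAA" * 510 + "TAA" + "ACGT" * 10
        g = AnnotatedMitogenome(id="mini", sequence=seq,
                                features=[GeneFeature("cox1", "PCG", 0, 1536, "J")])
        write_genbank(g, gb)
        text = gb.read_text()
        assert "1..1536" in text  # GenBank convention
        back = read_genbank(gb)
        assert (back.features[0].start, back.features[0].end) == (0, 1536)


def test_rotate_preserves_feature_sequences(default_genome):
    genome, _ = default_genome
    rot = rotate(genome, 4321)
    for f in genome.features:
        assert extract_feature_sequence(rot, rot.get(f.canonical_name)) == extract_feature_sequence(genome, f)
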