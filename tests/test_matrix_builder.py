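"""Supermatrix assembly: harvesting, codon-position filtering, writers."""

import random

import pytest

from mitochar.errors import AlignmentRequiredError, FrameError
from mitochar.matrix_builder import (
    build_supermatrix,
    concatenate,
    harvest,
    read_alignment,
    strip_third_positions,
    write_all_formats,
)


def _pad(blocks):
    """Trailing-gap pad so every block is rectangular (test-side 'alignment')."""
    for gene, per_taxon in blocks.items():
        lengths = [len(s) for s in per_taxon.values() if s is not None]
        m = max(lengths)
        m += (3 - m % 3) % 3
        for t, s in per_taxon.items():
            if s is not None:
                per_taxon[t] = s + "-" * (m - len(s))
    return blocks


class TestHarvest:
    def test_prt_yields_37_blocks_per_taxon(self, fixture_set):
        genomes = [g for g, _ in fixture_set]
        blocks = harvest(genomes, "PRT")
        assert len(blocks) == 37
        for per_taxon in blocks.values():
            assert set(per_taxon) == {g.id for g in genomes}

    def test_pcg_mode_is_13_blocks_with_frame_zero(self, fixture_set):
        genomes = [g for g, _ in fixture_set]
        blocks = harvest(genomes, "PCG")
        assert len(blocks) == 13
        for gene, per_taxon in blocks.items():
            for seq in per_taxon.values():
                assert len(seq) % 3 == 0  # stops and tails trimmed
                assert seq[:3] != ""

    def test_missing_gene_has_absence_record(self, fixture_set):
        from mitochar.genome_io import AnnotatedMitogenome

        genome = fixture_set[0][0]
        feats = [f for f in genome.features if f.canonical_name != "trnS1"]
        reduced = AnnotatedMitogenome(id="reduced", sequence=genome.sequence, features=feats)
        blocks = harvest([genome, reduced], "PRT")
        assert blocks["trnS1"]["reduced"] is None
        assert blocks["trnS1"][genome.id] is not None


class TestStripThirdPositions:
    def test_forced_ratio(self):
        out = strip_third_positions({"t1": "ATGCCCGGG"})
        assert out["t1"] == "ATCCGG"

    def test_matches_column_mask_oracle(self):
        rng = random.Random(3)
        for _ in range(30):
            n = 3 * rng.randint(2, 40)
            seqs = {
                f"t{k}": "".join(rng.choice("ACGT-") for _ in range(n)) for k in range(4)
            }
            out = strip_third_positions(seqs)
            for t, s in seqs.items():
                mask = [c for i, c in enumerate(s) if i % 3 != 2]
                assert out[t] == "".join(mask)

    def test_frame_error_on_bad_length(self):
        with pytest.raises(FrameError):
            strip_third_positions({"t1": "ATGC"})

    def test_ragged_block_rejected(self):
        with pytest.raises(AlignmentRequiredError):
            strip_third_positions({"t1": "ATGCCC", "t2": "ATG"})


class TestConcatenate:
    def test_two_taxa_two_blocks_partitions(self):
        blocks = {"cox1": {"a": "ATG", "b": "ATA"}, "cox2": {"a": "CCC", "b": "GGG"}}
        spec = concatenate(blocks, taxa=["a", "b"], mode="PCG")
        assert spec.total_length == 6
        assert spec.sequence_of("a") == "ATGCCC"
        assert [(n, s, e) for n, s, e, _ in spec.partition_table] == [
            ("cox1_pos1", 1, 3), ("cox1_pos2", 2, 3), ("cox1_pos3", 3, 3),
            ("cox2_pos1", 4, 6), ("cox2_pos2", 5, 6), ("cox2_pos3", 6, 6),
        ]

    def test_partition_rows_tile_total_length(self, fixture_set):
        genomes = [g for g, _ in fixture_set]
        spec = concatenate(_pad(harvest(genomes, "PRT")), taxa=[g.id for g in genomes], mode="PRT")
        covered = set()
        for name, start, end, kind in spec.partition_table:
            step = 3 if kind.startswith("codon") else 1
            covered.update(range(start, end + 1, step))
        assert covered == set(range(1, spec.total_length + 1))

    def test_missing_taxon_filled_with_gaps(self):
        blocks = {"cox1": {"a": "ATGTTT", "b": None}}
        spec = concatenate(blocks, taxa=["a", "b"], mode="PCG")
        assert spec.sequence_of("b") == "------"

    def test_ragged_block_refused(self):
        with pytest.raises(AlignmentRequiredError):
            concatenate({"cox1": {"a": "ATGTTT", "b": "ATG"}}, taxa=["a", "b"], mode="PCG")

    def test_12prt_length_identity(self, fixture_set):
        """12PRT total == PRT total - sum(PCG block length / 3)."""
        from mitochar.genome_io import PCG_NAMES

        genomes = [g for g, _ in fixture_set]
        taxa = [g.id for g in genomes]
        blocks = _pad(harvest(genomes, "PRT"))
        prt = concatenate(blocks, taxa=taxa, mode="PRT")
        prt12 = concatenate(blocks, taxa=taxa, mode="12PRT")
        pcg_third = sum(L // 3 for name, _, L in prt.gene_blocks if name in PCG_NAMES)
        assert prt12.total_length == prt.total_length - pcg_third


class TestWriters:
    @pytest.mark.parametrize("fmt,ext", [("fasta", "fasta"), ("phylip-relaxed", "phy"), ("nexus", "nex")])
    def test_round_trip_bit_exact(self, tmp_path, fixture_set, fmt, ext):
        genomes = [g for g, _ in fixture_set]
        spec = build_supermatrix(genomes, "PRT", pad_ragged=True)
        paths = write_all_formats(spec, tmp_path, "m")
        back = read_alignment(tmp_path / f"m.{ext}", fmt)
        assert list(back) == spec.taxa  # stable taxon order in every format
        for taxon in spec.taxa:
            assert back[taxon] == spec.sequence_of(taxon)

    def test_partition_files_agree(self, tmp_path, fixture_set):
        genomes = [g for g, _ in fixture_set]
        spec = build_supermatrix(genomes, "12PRT", pad_ragged=True)
        write_all_formats(spec, tmp_path, "m")
        raxml = (tmp_path / "m.partitions.txt").read_text().splitlines()
        nexus = (tmp_path / "m.nex").read_text()
        assert len(raxml) == len(spec.partition_table)
        for name, start, end, kind in spec.partition_table:
            step = "\\2" if kind.startswith("codon") else ""
            assert f"charset {name} = {start}-{end}{step};" in nexus
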