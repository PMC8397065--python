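"""Concatenated phylogenetic data matrices with codon-position partitions.

Three dataset modes are supported, mirroring standard mitogenomic practice:

* ``PCG``   - the 13 protein-coding genes;
* ``PRT``   - 13 PCGs + 2 rRNAs + 22 tRNAs (37 blocks);
* ``12PRT`` - as PRT but with third codon positions removed from the PCG
  blocks (third positions saturate fastest and are often discarded).

Alignment is deliberately external: blocks must arrive with equal per-taxon
lengths (a trailing-gap pad or a proper aligner), and ragged blocks raise.
PCG blocks are harvested with terminal stop codons and incomplete stop tails
trimmed, so their reading frame offset is always 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import AlignIO

from mitochar.codon_profile import STOP_CODONS
from mitochar.errors import AlignmentRequiredError, FrameError
from mitochar.gene_layout import LEPIDOPTERAN_GENE_ORDER
from mitochar.genome_io import (
    PCG_NAMES,
    ROLE_PCG,
    ROLE_RRNA,
    ROLE_TRNA,
    AnnotatedMitogenome,
    extract_feature_sequence,
)

logger = logging.getLogger(__name__)

MODES = ("PCG", "PRT", "12PRT")
GAP = "-"

# Canonical mitochondrial block order (gene order on the genome, not alphabetical).
_CANONICAL_BLOCK_ORDER = tuple(name for name, _ in LEPIDOPTERAN_GENE_ORDER if name != "AT-rich")

PartitionRow = tuple[str, int, int, str]  # (block name, start 1-based, end 1-based incl., kind)


@dataclass
class SupermatrixSpec:
    """A concatenated matrix: taxa, ordered gene blocks, and partition rows."""

    mode: str
    taxa: list[str]
    gene_blocks: list[tuple[str, dict[str, str], int]]  # (gene, taxon->sequence, block length)
    partition_table: list[PartitionRow] = field(default_factory=list)
    aligned: bool = True

    @property
    def total_length(self) -> int:
        return sum(length for _, _, length in self.gene_blocks)

    def sequence_of(self, taxon: str) -> str:
        return "".join(seqs[taxon] for _, seqs, _ in self.gene_blocks)


def harvest(genomes: list[AnnotatedMitogenome], mode: str) -> dict[str, dict[str, str]]:
    """Per-gene coding-sense sequence sets across taxa (unaligned).

    PCG sequences are trimmed of their terminal complete stop codon and of
    any incomplete stop tail so every PCG block has frame offset 0. A gene
    absent from a taxon yields an explicit ``None`` record (downstream it
    becomes an all-gap row); a gene absent from every taxon drops its block
    with a warning.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    roles = (ROLE_PCG,) if mode == "PCG" else (ROLE_PCG, ROLE_RRNA, ROLE_TRNA)
    wanted = [n for n in _CANONICAL_BLOCK_ORDER if (n in PCG_NAMES) or mode != "PCG"]
    sets: dict[str, dict[str, str]] = {}
    for gene in wanted:
        per_taxon: dict[str, str | None] = {}
        for g in genomes:
            feat = g.get(gene)
            if feat is None or feat.role not in roles:
                per_taxon[g.id] = None
                continue
            seq = extract_feature_sequence(g, feat)
            if feat.role == ROLE_PCG:
                seq = seq[: len(seq) - len(seq) % 3]  # incomplete stop tail
                if seq[-3:] in STOP_CODONS:
                    seq = seq[:-3]
            per_taxon[g.id] = seq
        if all(v is None for v in per_taxon.values()):
            logger.warning("gene %s absent in all taxa; block dropped", gene)
            continue
        sets[gene] = per_taxon
    return sets


def strip_third_positions(aligned_block: dict[str, str], frame_offset: int = 0) -> dict[str, str]:
    """Keep alignment columns at codon positions 1 and 2 (gaps count as columns)."""
    lengths = {len(s) for s in aligned_block.values()}
    if len(lengths) != 1:
        raise AlignmentRequiredError("ragged block: align before stripping positions")
    (length,) = lengths
    if (length - frame_offset) % 3:
        raise FrameError(f"block length {length} minus offset {frame_offset} not divisible by 3")
    keep = [i for i in range(length) if i < frame_offset or (i - frame_offset) % 3 != 2]
    return {taxon: "".join(seq[i] for i in keep) for taxon, seq in aligned_block.items()}


def concatenate(
    blocks: dict[str, dict[str, str]],
    taxa: list[str] | None = None,
    mode: str = "PRT",
    aligned: bool = True,
) -> SupermatrixSpec:
    """Concatenate gene blocks into a supermatrix with a partition table.

    ``blocks`` maps gene name to taxon->sequence (``None`` = gene missing in
    that taxon, filled with gaps). Within each block all present sequences
    must be equal length; otherwise the tool refuses (it never aligns).
    Blocks are emitted in canonical mitochondrial gene order; taxon order is
    the input order and identical in every emitted format. In 12PRT mode the
    PCG blocks are reduced to first+second codon positions before
    concatenation.
    """
    if taxa is None:
        taxa = list(next(iter(blocks.values())).keys())
    ordered = [g for g in _CANONICAL_BLOCK_ORDER if g in blocks]
    gene_blocks: list[tuple[str, dict[str, str], int]] = []
    partition: list[PartitionRow] = []
    offset = 0
    for gene in ordered:
        per_taxon = dict(blocks[gene])
        lengths = {len(s) for s in per_taxon.values() if s is not None}
        if len(lengths) > 1:
            raise AlignmentRequiredError(
                f"block {gene}: per-taxon lengths differ {sorted(lengths)}; align externally first"
            )
        (length,) = lengths
        if mode == "12PRT" and gene in PCG_NAMES:
            present = {t: s for t, s in per_taxon.items() if s is not None}
            stripped = strip_third_positions(present)
            per_taxon = {t: stripped.get(t) for t in per_taxon}
            length = length - length // 3
        filled = {t: (per_taxon.get(t) or GAP * length) for t in taxa}
        gene_blocks.append((gene, filled, length))
        start, end = offset + 1, offset + length
        if gene in PCG_NAMES and mode != "12PRT":
            partition.append((f"{gene}_pos1", start, end, "codon1"))
            partition.append((f"{gene}_pos2", start + 1, end, "codon2"))
            partition.append((f"{gene}_pos3", start + 2, end, "codon3"))
        elif gene in PCG_NAMES:
            partition.append((f"{gene}_pos1", start, end, "codon1"))
            partition.append((f"{gene}_pos2", start + 1, end, "codon2"))
        else:
            partition.append((gene, start, end, "rna"))
        offset = end
    return SupermatrixSpec(mode=mode, taxa=list(taxa), gene_blocks=gene_blocks,
                           partition_table=partition, aligned=aligned)


def build_supermatrix(genomes: list[AnnotatedMitogenome], mode: str,
                      pad_ragged: bool = False) -> SupermatrixSpec:
    """harvest + concatenate; optionally pad ragged blocks with trailing gaps.

    Padding is a crude stand-in for a real alignment and is off by default;
    the result is flagged ``aligned=False`` when padding was applied.
    """
    blocks = harvest(genomes, mode)
    padded = False
    for gene, per_taxon in blocks.items():
        lengths = {len(s) for s in per_taxon.values() if s is not None}
        if len(lengths) > 1:
            if not pad_ragged:
                raise AlignmentRequiredError(f"block {gene} is ragged; align externally or pad_ragged=True")
            m = max(lengths)
            target = m + ((3 - m % 3) % 3 if gene in PCG_NAMES else 0)
            for t, s in per_taxon.items():
                if s is not None:
                    per_taxon[t] = s + GAP * (target - len(s))
            padded = True
        elif gene in PCG_NAMES:
            (m,) = lengths
            if m % 3:
                raise FrameError(f"block {gene}: length {m} not divisible by 3 after stop trimming")
    taxa = [g.id for g in genomes]
    return concatenate(blocks, taxa=taxa, mode=mode, aligned=not padded)


# --- writers / readers -------------------------------------------------------

def write_fasta_matrix(spec: SupermatrixSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxon in spec.taxa:
            fh.write(f">{taxon}\n{spec.sequence_of(taxon)}\n")


def write_phylip_matrix(spec: SupermatrixSpec, path: str | Path) -> None:
    """Relaxed PHYLIP: full taxon names, two-space separator."""
    with open(path, "w") as fh:
        fh.write(f" {len(spec.taxa)} {spec.total_length}\n")
        for taxon in spec.taxa:
            fh.write(f"{taxon}  {spec.sequence_of(taxon)}\n")


def write_nexus_matrix(spec: SupermatrixSpec, path: str | Path) -> None:
    """NEXUS with a sets block mirroring the partition table."""
    with open(path, "w") as fh:
        fh.write("#NEXUS\n")
        fh.write("begin data;\n")
        fh.write(f"  dimensions ntax={len(spec.taxa)} nchar={spec.total_length};\n")
        fh.write("  format datatype=dna missing=? gap=-;\n")
        fh.write("  matrix\n")
        for taxon in spec.taxa:
            fh.write(f"    {taxon}  {spec.sequence_of(taxon)}\n")
        fh.write("  ;\nend;\n")
        fh.write("begin sets;\n")
        for name, start, end, kind in spec.partition_table:
            step = "\\3" if kind.startswith("codon") and spec.mode != "12PRT" else (
                "\\2" if kind.startswith("codon") else "")
            fh.write(f"  charset {name} = {start}-{end}{step};\n")
        fh.write("end;\n")


def write_raxml_partitions(spec: SupermatrixSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, start, end, kind in spec.partition_table:
            step = "\\3" if kind.startswith("codon") and spec.mode != "12PRT" else (
                "\\2" if kind.startswith("codon") else "")
            fh.write(f"DNA, {name} = {start}-{end}{step}\n")


def read_alignment(path: str | Path, fmt: str) -> dict[str, str]:
    """Read an emitted matrix back (fmt: fasta | phylip-relaxed | nexus)."""
    aln = AlignIO.read(str(path), fmt)
    return {rec.id: str(rec.seq).upper() for rec in aln}


def write_all_formats(spec: SupermatrixSpec, out_dir: str | Path, stem: str) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out_dir / f"{stem}.fasta",
        "phylip": out_dir / f"{stem}.phy",
        "nexus": out_dir / f"{stem}.nex",
        "raxml": out_dir / f"{stem}.partitions.txt",
    }
    write_fasta_matrix(spec, paths["fasta"])
    write_phylip_matrix(spec, paths["phylip"])
    write_nexus_matrix(spec, paths["nexus"])
    write_raxml_partitions(spec, paths["raxml"])
    return paths
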