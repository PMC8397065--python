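"""Nucleotide composition and strand-skew statistics.

AT-skew = (A - T) / (A + T) and GC-skew = (G - C) / (G + C), computed on the
majority (J) strand for genome-level regions and on coding-sense sequence for
gene-class regions. N bases are excluded from all denominators.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from mitochar.errors import UndefinedCompositionError
from mitochar.genome_io import (
    ROLE_CR,
    ROLE_PCG,
    ROLE_RRNA,
    ROLE_TRNA,
    AnnotatedMitogenome,
    extract_feature_sequence,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CompositionStats:
    """Base counts, percentages, A+T content and skews for one region."""

    region_label: str
    count_A: int
    count_T: int
    count_G: int
    count_C: int
    count_N: int

    @property
    def total(self) -> int:
        """Non-N length the percentages refer to."""
        return self.count_A + self.count_T + self.count_G + self.count_C

    @property
    def pct_A(self) -> float:
        return 100.0 * self.count_A / self.total

    @property
    def pct_T(self) -> float:
        return 100.0 * self.count_T / self.total

    @property
    def pct_G(self) -> float:
        return 100.0 * self.count_G / self.total

    @property
    def pct_C(self) -> float:
        return 100.0 * self.count_C / self.total

    @property
    def at_content(self) -> float:
        return self.pct_A + self.pct_T

    @property
    def gc_content(self) -> float:
        return self.pct_G + self.pct_C

    @property
    def at_skew(self) -> float:
        return at_skew(self.count_A, self.count_T)

    @property
    def gc_skew(self) -> float:
        return gc_skew(self.count_G, self.count_C)

    def as_row(self) -> dict:
        """Report row with the conventional printed precision (1 d.p. percent, 4 d.p. skew)."""
        return {
            "region": self.region_label,
            "length_bp": self.total + self.count_N,
            "pct_A": round(self.pct_A, 1),
            "pct_T": round(self.pct_T, 1),
            "pct_G": round(self.pct_G, 1),
            "pct_C": round(self.pct_C, 1),
            "at_content": round(self.at_content, 1),
            "at_skew": round(self.at_skew, 4),
            "gc_skew": round(self.gc_skew, 4),
            "count_N": self.count_N,
        }


def at_skew(count_a: float, count_t: float) -> float:
    """(A - T) / (A + T); antisymmetric under exchange of the two counts."""
    denom = count_a + count_t
    if denom <= 0:
        raise UndefinedCompositionError("AT-skew undefined: A + T is zero")
    return (count_a - count_t) / denom


def gc_skew(count_g: float, count_c: float) -> float:
    """(G - C) / (G + C)."""
    denom = count_g + count_c
    if denom <= 0:
        raise UndefinedCompositionError("GC-skew undefined: G + C is zero")
    return (count_g - count_c) / denom


def base_composition(seq: str, label: str = "") -> CompositionStats:
    """Count bases of ``seq`` (A/C/G/T/N alphabet); percentages over non-N positions."""
    if not seq:
        raise UndefinedCompositionError(f"{label or 'region'}: empty sequence")
    counts = Counter(seq.upper())
    unexpected = set(counts) - set("ACGTN")
    if unexpected:
        raise UndefinedCompositionError(f"{label or 'region'}: unexpected characters {sorted(unexpected)}")
    stats = CompositionStats(
        region_label=label,
        count_A=counts.get("A", 0),
        count_T=counts.get("T", 0),
        count_G=counts.get("G", 0),
        count_C=counts.get("C", 0),
        count_N=counts.get("N", 0),
    )
    if stats.total == 0:
        raise UndefinedCompositionError(f"{label or 'region'}: all-N sequence has no defined composition")
    return stats


def merge(stats: list[CompositionStats], label: str) -> CompositionStats:
    """Count-weighted merge; exactly equals composition of the concatenation."""
    return CompositionStats(
        region_label=label,
        count_A=sum(s.count_A for s in stats),
        count_T=sum(s.count_T for s in stats),
        count_G=sum(s.count_G for s in stats),
        count_C=sum(s.count_C for s in stats),
        count_N=sum(s.count_N for s in stats),
    )


def pcg_codon_position_sequences(genome: AnnotatedMitogenome) -> tuple[str, str, str]:
    """Concatenated 1st/2nd/3rd codon-position bases over all PCGs (coding sense).

    Each gene's trailing incomplete codon (the 1- or 2-bp remainder feeding an
    incomplete stop) is dropped so positions 1-3 tile complete codons.
    """
    pos = ["", "", ""]
    for f in genome.features_by_role(ROLE_PCG):
        seq = extract_feature_sequence(genome, f)
        n = len(seq) - len(seq) % 3
        seq = seq[:n]
        pos[0] += seq[0::3]
        pos[1] += seq[1::3]
        pos[2] += seq[2::3]
    return pos[0], pos[1], pos[2]


def region_composition_table(genome: AnnotatedMitogenome) -> list[CompositionStats]:
    """One composition row per region class of the genome.

    Rows: whole genome (J strand), concatenated PCGs (coding sense), PCG codon
    positions 1/2/3, concatenated tRNAs, concatenated rRNAs, AT-rich region.
    A missing region class drops its row with a warning.
    """
    rows = [base_composition(genome.sequence, "whole genome")]

    pcgs = genome.features_by_role(ROLE_PCG)
    if pcgs:
        concat = "".join(extract_feature_sequence(genome, f) for f in pcgs)
        rows.append(base_composition(concat, "PCGs"))
        for i, seq in enumerate(pcg_codon_position_sequences(genome), start=1):
            rows.append(base_composition(seq, f"PCGs codon position {i}"))
    else:
        logger.warning("%s: no PCGs annotated; PCG rows omitted", genome.id)

    trnas = genome.features_by_role(ROLE_TRNA)
    if trnas:
        rows.append(base_composition("".join(extract_feature_sequence(genome, f) for f in trnas), "tRNAs"))
    else:
        logger.warning("%s: no tRNAs annotated; tRNA row omitted", genome.id)

    rrnas = genome.features_by_role(ROLE_RRNA)
    if rrnas:
        rows.append(base_composition("".join(extract_feature_sequence(genome, f) for f in rrnas), "rRNAs"))
    else:
        logger.warning("%s: no rRNAs annotated; rRNA row omitted", genome.id)

    cr = genome.features_by_role(ROLE_CR)
    if cr:
        rows.append(base_composition(extract_feature_sequence(genome, cr[0]), "AT-rich region"))
    else:
        logger.warning("%s: no AT-rich region annotated; row omitted", genome.id)

    return rows


def composition_dataframe(genome: AnnotatedMitogenome) -> pd.DataFrame:
    df = pd.DataFrame([s.as_row() for s in region_composition_table(genome)])
    df.insert(0, "genome", genome.id)
    return df
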