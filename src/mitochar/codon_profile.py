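"""Codon accounting under the invertebrate mitochondrial genetic code.

Relative to the standard code, this code (NCBI translation table 5) reads
ATA as Met, TGA as Trp and AGA/AGG as Ser, leaving TAA and TAG as the only
stop codons. RSCU families split leucine into Leu1 (CTN) and Leu2 (TTA/TTG)
and serine into Ser1 (AGN, four codons here) and Ser2 (TCN), the
conventional labeling for mitochondrial codon-usage plots.

RSCU(c) = count(c) * family_size / family_total: the observed count divided
by the count expected if all synonymous codons of the family were used
equally. Values sum to the family size within each family.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from collections import Counter
from typing import Iterable, Mapping

import pandas as pd

from mitochar.errors import FrameError
from mitochar.genome_io import ROLE_PCG, AnnotatedMitogenome, GeneFeature, extract_feature_sequence

BASES = "TCAG"
CODONS = tuple("".join(c) for c in itertools.product(BASES, repeat=3))

# NCBI table 5 amino acids in TCAG codon order.
_TAB5_AAS = "FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIMMTTTTNNKKSSSSVVVVAAAADDEEGGGG"
TABLE5 = dict(zip(CODONS, _TAB5_AAS))
STOP_CODONS = ("TAA", "TAG")
STANDARD_STARTS = ("ATA", "ATT", "ATC", "ATG")
ALTERNATIVE_STARTS = ("CGA",)


def _family_of(codon: str) -> str | None:
    aa = TABLE5[codon]
    if aa == "*":
        return None
    if aa == "L":
        return "Leu2" if codon in ("TTA", "TTG") else "Leu1"
    if aa == "S":
        return "Ser1" if codon.startswith("AG") else "Ser2"
    names = {
        "F": "Phe", "I": "Ile", "M": "Met", "V": "Val", "P": "Pro", "T": "Thr",
        "A": "Ala", "Y": "Tyr", "H": "His", "Q": "Gln", "N": "Asn", "K": "Lys",
        "D": "Asp", "E": "Glu", "C": "Cys", "W": "Trp", "R": "Arg", "G": "Gly",
    }
    return names[aa]


FAMILY_OF: dict[str, str] = {c: f for c in CODONS if (f := _family_of(c)) is not None}
FAMILIES: dict[str, tuple[str, ...]] = {}
for _c, _f in FAMILY_OF.items():
    FAMILIES.setdefault(_f, ())
FAMILIES = {f: tuple(c for c in CODONS if FAMILY_OF.get(c) == f) for f in FAMILIES}


class InternalStopWarning(UserWarning):
    """A protein-coding sequence translates with stop codons before its end."""


def translate_tab5(codon_seq: str, gene: str = "") -> str:
    """Translate a coding-sense nucleotide string under translation table 5.

    The length must be divisible by 3 (callers truncate a flagged incomplete
    stop tail first). Internal stops are translated as '*' and reported as a
    warning listing their codon indices; they are never silently dropped.
    """
    seq = codon_seq.upper()
    if len(seq) % 3:
        raise FrameError(f"{gene or 'sequence'}: length {len(seq)} not divisible by 3")
    protein = []
    internal_stops = []
    n_codons = len(seq) // 3
    for i in range(n_codons):
        codon = seq[3 * i: 3 * i + 3]
        aa = TABLE5.get(codon, "X")
        if aa == "*" and i < n_codons - 1:
            internal_stops.append(i)
        protein.append(aa)
    if internal_stops:
        warnings.warn(
            f"{gene or 'sequence'}: internal stop codon(s) at codon index(es) {internal_stops}",
            InternalStopWarning,
            stacklevel=2,
        )
    return "".join(protein)


@dataclass(frozen=True)
class StartStopCall:
    """Start/stop classification for one protein-coding gene."""

    gene: str
    start_codon: str
    stop_codon: str  # TAA, TAG, "T-", "TA-", or a flagged nonstandard triplet
    complete_codon_count: int
    flags: tuple[str, ...] = ()

    @property
    def incomplete_tail_length(self) -> int:
        return {"T-": 1, "TA-": 2}.get(self.stop_codon, 0)


def classify_start_stop(genome: AnnotatedMitogenome, pcg_feature: GeneFeature) -> StartStopCall:
    """Classify a PCG's initiation and termination codons.

    The stop is the final complete triplet when that triplet is TAA/TAG;
    otherwise the gene length remainder mod 3 dictates an incomplete stop
    (1 -> "T-", 2 -> "TA-"), the truncated codon completed to TAA by
    post-transcriptional polyadenylation. cox1-style CGA starts are accepted
    and flagged "alternative-start"; any other non-ATN triplet is flagged
    "nonstandard-start".
    """
    if pcg_feature.role != ROLE_PCG:
        raise ValueError(f"{pcg_feature.canonical_name}: not a protein-coding gene")
    seq = extract_feature_sequence(genome, pcg_feature)
    if len(seq) < 6:
        raise FrameError(f"{pcg_feature.canonical_name}: too short to classify ({len(seq)} bp)")
    flags: list[str] = []
    start = seq[:3]
    if start in ALTERNATIVE_STARTS:
        flags.append("alternative-start")
    elif start not in STANDARD_STARTS:
        flags.append("nonstandard-start")
    rem = len(seq) % 3
    n_complete = len(seq) // 3
    if rem == 0:
        last = seq[-3:]
        if last in STOP_CODONS:
            stop = last
        else:
            stop = last
            flags.append("nonstandard-stop")
    elif rem == 1:
        stop = "T-"
        if seq[-1] != "T":
            flags.append("nonstandard-stop")
    else:
        stop = "TA-"
        if seq[-2:] != "TA":
            flags.append("nonstandard-stop")
    return StartStopCall(
        gene=pcg_feature.canonical_name,
        start_codon=start,
        stop_codon=stop,
        complete_codon_count=n_complete,
        flags=tuple(flags),
    )


def rscu(profile_counts: Mapping[str, int]) -> dict[str, float]:
    """Relative synonymous codon usage from per-codon counts.

    Stop codons are excluded; a synonymous family with zero total usage has
    RSCU 0 for all its codons. For each used family the values sum exactly
    to the family size.
    """
    values: dict[str, float] = {}
    for family, codons in FAMILIES.items():
        total = sum(profile_counts.get(c, 0) for c in codons)
        for c in codons:
            values[c] = len(codons) * profile_counts.get(c, 0) / total if total else 0.0
    return values


def count_codons(coding_seqs: Iterable[str], drop_terminal_stop: bool = True) -> Counter:
    """Tally complete codons over coding-sense sequences.

    Incomplete trailing codons are dropped; a final complete TAA/TAG is
    excluded by default (it belongs in the stop-codon report, not in RSCU
    families).
    """
    counts: Counter = Counter()
    for seq in coding_seqs:
        seq = seq.upper()
        n = len(seq) - len(seq) % 3
        seq = seq[:n]
        if drop_terminal_stop and seq[-3:] in STOP_CODONS:
            seq = seq[:-3]
        for i in range(0, len(seq), 3):
            counts[seq[i: i + 3]] += 1
    return counts


@dataclass
class CodonProfile:
    """Per-codon counts and RSCU over one or more protein-coding sequences."""

    counts: Counter = field(default_factory=Counter)

    @classmethod
    def from_sequences(cls, coding_seqs: Iterable[str]) -> "CodonProfile":
        return cls(counts=count_codons(coding_seqs))

    @classmethod
    def from_genome(cls, genome: AnnotatedMitogenome) -> "CodonProfile":
        seqs = [extract_feature_sequence(genome, f) for f in genome.features_by_role(ROLE_PCG)]
        return cls.from_sequences(seqs)

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    @property
    def rscu(self) -> dict[str, float]:
        return rscu(self.counts)

    def to_dataframe(self) -> pd.DataFrame:
        """64-row table: codon, amino acid, family, count, RSCU."""
        r = self.rscu
        rows = [
            {
                "codon": c,
                "amino_acid": TABLE5[c],
                "family": FAMILY_OF.get(c, "Stop"),
                "count": self.counts.get(c, 0),
                "rscu": round(r.get(c, 0.0), 2) if c in r else float("nan"),
            }
            for c in CODONS
        ]
        return pd.DataFrame(rows)


def start_stop_table(genome: AnnotatedMitogenome) -> pd.DataFrame:
    rows = []
    for f in genome.features_by_role(ROLE_PCG):
        call = classify_start_stop(genome, f)
        rows.append(
            {
                "genome": genome.id,
                "gene": call.gene,
                "length_bp": f.length_bp,
                "start_codon": call.start_codon,
                "stop_codon": call.stop_codon,
                "complete_codons": call.complete_codon_count,
                "flags": ";".join(call.flags),
            }
        )
    return pd.DataFrame(rows)


def pcg_length_report(genome: AnnotatedMitogenome) -> dict:
    """Per-gene PCG lengths (bp), their total, and any absent genes."""
    from mitochar.genome_io import PCG_NAMES

    lengths: dict[str, int] = {}
    absent = []
    for name in PCG_NAMES:
        feat = genome.get(name)
        if feat is None or feat.role != ROLE_PCG:
            absent.append(name)
        else:
            lengths[name] = feat.length_bp
    return {"lengths": lengths, "total_bp": sum(lengths.values()), "absent": absent}
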