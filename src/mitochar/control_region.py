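"""Structural elements of the AT-rich (control) region.

The major non-coding region of the insect mitogenome sits between rrnS and
trnM and carries the origin of minority-strand replication: the pentamer
ATAGA followed by a long poly-T stretch. It also accumulates (AT)n
dinucleotide repeats and microsatellite-like runs anchored downstream of the
motif ATTTA. All scanners here are exact-match: at control-region scale
(hundreds of bp) exhaustive exact search is tractable and fully testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from mitochar.errors import AbsentControlRegionError
from mitochar.genome_io import ROLE_CR, AnnotatedMitogenome, GeneFeature, extract_feature_sequence

ORIGIN_MOTIF = "ATAGA"
MICROSAT_ANCHOR = "ATTTA"


@dataclass(frozen=True)
class TandemRepeat:
    """A perfect tandem run: ``unit`` repeated ``copies`` times from ``start``."""

    unit: str
    copies: int
    start: int
    span: int  # total bases covered, including any partial trailing copy

    @property
    def end(self) -> int:
        return self.start + self.span


@dataclass
class CrElements:
    """Detected structural elements of one control region."""

    genome_id: str
    cr_start: int
    cr_end: int
    origin_motif: tuple[int, int] | None  # (ATAGA position, poly-T length), CR-relative
    dinucleotide_repeats: list[tuple[str, int, int]]  # (unit "AT", copies, position)
    atta_microsatellites: list[TandemRepeat]
    tandem_repeats: list[TandemRepeat]

    @property
    def cr_length(self) -> int:
        return self.cr_end - self.cr_start


def locate_at_rich(genome: AnnotatedMitogenome) -> tuple[int, int]:
    """The AT-rich region interval, 0-based half-open (end may wrap past L).

    Uses the explicit annotation when present (D-loop or misc_feature mapped
    to the AT-rich role); otherwise falls back to the inter-feature gap from
    the end of rrnS to the start of trnM, modulo the origin.
    """
    cr = genome.features_by_role(ROLE_CR)
    if cr:
        return cr[0].start, cr[0].end
    rrns = genome.get("rrnS")
    trnm = genome.get("trnM")
    if rrns is None or trnm is None:
        raise AbsentControlRegionError(f"{genome.id}: no AT-rich annotation and rrnS/trnM not both present")
    L = genome.length_bp
    start = rrns.end % L
    end = trnm.start
    if end < start:
        end += L
    if end == start:
        raise AbsentControlRegionError(f"{genome.id}: zero-length rrnS-trnM gap and no AT-rich annotation")
    return start, end


def find_origin_motif(cr_seq: str, motif: str = ORIGIN_MOTIF) -> tuple[int, int] | None:
    """Replication-origin element: ``motif`` plus its trailing poly-T run.

    Scans the majority-strand control-region sequence for every occurrence
    of the motif and measures the maximal run of consecutive T immediately
    after it; the occurrence with the longest run wins, ties going to the
    first. Absence is a valid result (None).
    """
    cr_seq = cr_seq.upper()
    best: tuple[int, int] | None = None
    pos = cr_seq.find(motif)
    while pos != -1:
        i = pos + len(motif)
        j = i
        while j < len(cr_seq) and cr_seq[j] == "T":
            j += 1
        poly_t = j - i
        if best is None or poly_t > best[1]:
            best = (pos, poly_t)
        pos = cr_seq.find(motif, pos + 1)
    return best


def find_dinucleotide_repeats(cr_seq: str, min_copies: int = 4) -> list[tuple[str, int, int]]:
    """Maximal (AT)n runs with at least ``min_copies`` copies.

    A run is a maximal strictly alternating A/T block; phase-shifted (TA)n
    runs are reported under the canonical unit "AT" at the block start, with
    copy number floor(block length / 2).
    """
    if min_copies < 2:
        raise ValueError("min_copies must be >= 2")
    s = cr_seq.upper()
    runs: list[tuple[str, int, int]] = []
    i = 0
    n = len(s)
    while i < n:
        if s[i] not in "AT":
            i += 1
            continue
        j = i + 1
        while j < n and s[j] in "AT" and s[j] != s[j - 1]:
            j += 1
        block_len = j - i
        copies = block_len // 2
        if copies >= min_copies:
            runs.append(("AT", copies, i))
        i = j
    return runs


def _primitive(unit: str) -> bool:
    for p in range(1, len(unit)):
        if len(unit) % p == 0 and unit == unit[:p] * (len(unit) // p):
            return False
    return True


def find_tandem_repeats(seq: str, max_unit: int = 6, min_copies: float = 3) -> list[TandemRepeat]:
    """Exhaustive exact tandem-repeat search for control-region-scale input.

    For every unit length u <= max_unit the maximal perfect runs are found
    via the self-match profile s[i] == s[i+u]; a run is reported once, at
    its smallest primitive unit, when its complete-copy count reaches
    ``min_copies``. No mismatches or indels are tolerated.
    """
    if max_unit > 50:
        raise ValueError("max_unit must be <= 50")
    if len(seq) > 10_000:
        raise ValueError("sequence too long for exhaustive scan (control-region scale expected)")
    s = seq.upper()
    n = len(s)
    found: list[TandemRepeat] = []
    for u in range(1, min(max_unit, n // 2) + 1):
        i = 0
        while i < n - u:
            if s[i] != s[i + u]:
                i += 1
                continue
            j = i
            while j < n - u and s[j] == s[j + u]:
                j += 1
            # matched stretch [i, j) of length j-i, total span j-i+u
            span = j - i + u
            copies = span // u
            unit = s[i: i + u]
            if copies >= min_copies and _primitive(unit):
                found.append(TandemRepeat(unit=unit, copies=copies, start=i, span=span))
            i = j + 1
    found.sort(key=lambda r: (r.start, len(r.unit)))
    # drop runs fully contained in an equal-or-longer reported run of smaller unit
    kept: list[TandemRepeat] = []
    for r in found:
        redundant = any(
            k.start <= r.start and k.end >= r.end and len(k.unit) < len(r.unit)
            for k in found
            if k is not r
        )
        if not redundant:
            kept.append(r)
    return kept


def find_microsatellites_after_motif(
    cr_seq: str,
    anchor: str = MICROSAT_ANCHOR,
    window: int = 10,
    max_unit: int = 6,
    min_copies: float = 3,
) -> list[TandemRepeat]:
    """Tandem repeats starting within ``window`` bp downstream of each anchor.

    Reported positions are absolute within ``cr_seq``. The default anchor is
    the conserved pentamer ATTTA.
    """
    if not anchor:
        raise ValueError("anchor must be nonempty")
    s = cr_seq.upper()
    out: list[TandemRepeat] = []
    pos = s.find(anchor)
    while pos != -1:
        origin = pos + len(anchor)
        for rep in find_tandem_repeats(s[origin:], max_unit=max_unit, min_copies=min_copies):
            if rep.start < window:
                out.append(TandemRepeat(rep.unit, rep.copies, origin + rep.start, rep.span))
        pos = s.find(anchor, pos + 1)
    return out


def analyze_control_region(
    genome: AnnotatedMitogenome,
    min_at_copies: int = 4,
    max_unit: int = 6,
    min_tandem_copies: float = 3,
) -> CrElements:
    """Full element scan of a genome's AT-rich region (CR-relative positions)."""
    start, end = locate_at_rich(genome)
    feature = GeneFeature(canonical_name="AT-rich", role=ROLE_CR, start=start % genome.length_bp,
                          end=(start % genome.length_bp) + (end - start), strand="J")
    cr_seq = extract_feature_sequence(genome, feature)
    return CrElements(
        genome_id=genome.id,
        cr_start=start,
        cr_end=end,
        origin_motif=find_origin_motif(cr_seq),
        dinucleotide_repeats=find_dinucleotide_repeats(cr_seq, min_copies=min_at_copies),
        atta_microsatellites=find_microsatellites_after_motif(
            cr_seq, max_unit=max_unit, min_copies=min_tandem_copies
        ),
        tandem_repeats=find_tandem_repeats(cr_seq, max_unit=max_unit, min_copies=min_tandem_copies),
    )


def elements_as_dict(el: CrElements) -> dict:
    """JSON-ready element report."""
    return {
        "genome": el.genome_id,
        "cr_interval": [el.cr_start, el.cr_end],
        "cr_length_bp": el.cr_length,
        "origin_motif": (
            None
            if el.origin_motif is None
            else {"position": el.origin_motif[0], "poly_t_length": el.origin_motif[1]}
        ),
        "dinucleotide_repeats": [
            {"unit": u, "copies": n, "position": p} for u, n, p in el.dinucleotide_repeats
        ],
        "atta_microsatellites": [
            {"unit": r.unit, "copies": r.copies, "position": r.start, "span": r.span}
            for r in el.atta_microsatellites
        ],
        "tandem_repeats": [
            {"unit": r.unit, "copies": r.copies, "position": r.start, "span": r.span}
            for r in el.tandem_repeats
        ],
    }
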