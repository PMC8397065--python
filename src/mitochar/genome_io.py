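"""Reading, writing and normalizing annotated circular mitogenomes.

Internal coordinates are 0-based half-open on the majority (J) strand.
GenBank I/O converts to/from the flat file's 1-based inclusive convention.
A feature that spans the circular origin is stored with ``end > length_bp``
and interpreted modulo the genome length, which keeps every interval
contiguous for downstream arithmetic.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from mitochar.errors import CoordinateError, ParseError

logger = logging.getLogger(__name__)

PCG_NAMES = (
    "cox1", "cox2", "cox3", "atp6", "atp8",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "Cytb",
)
TRNA_NAMES = (
    "trnM", "trnI", "trnQ", "trnW", "trnC", "trnY", "trnL2", "trnK", "trnD",
    "trnG", "trnA", "trnR", "trnN", "trnS1", "trnE", "trnF", "trnH", "trnT",
    "trnP", "trnS2", "trnL1", "trnV",
)
RRNA_NAMES = ("rrnL", "rrnS")
AT_RICH = "AT-rich"
CANONICAL_GENES = PCG_NAMES + TRNA_NAMES + RRNA_NAMES

ROLE_PCG = "PCG"
ROLE_TRNA = "tRNA"
ROLE_RRNA = "rRNA"
ROLE_CR = "control-region"
ROLE_UNKNOWN = "unknown"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_VALID_SEQ = re.compile(r"^[ACGTN]+$")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """One named gene or region with circular coordinates.

    ``start`` is 0-based inclusive; ``end`` is exclusive and may exceed the
    genome length to encode a wrap-around interval. ``strand`` is ``J``
    (majority) or ``N`` (minority); the minority strand carries the gene on
    the reverse complement.
    """

    canonical_name: str
    role: str
    start: int
    end: int
    strand: str = "J"
    raw_name: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise CoordinateError(
                f"feature {self.canonical_name}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("J", "N"):
            raise CoordinateError(f"feature {self.canonical_name}: strand must be J or N")

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    def wraps(self, genome_length: int) -> bool:
        return self.end > genome_length


@dataclass
class AnnotatedMitogenome:
    """A circular mitogenome: majority-strand sequence plus ordered features."""

    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    is_circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ParseError(f"{self.id}: empty sequence")
        if not _VALID_SEQ.match(self.sequence):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise ParseError(f"{self.id}: ambiguity codes other than N are not supported: {bad}")
        L = self.length_bp
        for f in self.features:
            if not (0 <= f.start < L):
                raise CoordinateError(f"{self.id}/{f.canonical_name}: start {f.start} outside [0, {L})")
            if f.length_bp > L:
                raise CoordinateError(f"{self.id}/{f.canonical_name}: feature longer than genome")
        cr = [f for f in self.features if f.role == ROLE_CR]
        if len(cr) > 1:
            raise CoordinateError(f"{self.id}: more than one AT-rich region annotated")
        self.features.sort(key=lambda f: (f.start, f.end))

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def features_by_role(self, role: str) -> list[GeneFeature]:
        return [f for f in self.features if f.role == role]

    def get(self, canonical_name: str) -> GeneFeature | None:
        for f in self.features:
            if f.canonical_name == canonical_name:
                return f
        return None


# --- gene-name normalization -------------------------------------------------

_AA3_TO_TRN = {
    "ala": "trnA", "arg": "trnR", "asn": "trnN", "asp": "trnD", "cys": "trnC",
    "gln": "trnQ", "glu": "trnE", "gly": "trnG", "his": "trnH", "ile": "trnI",
    "lys": "trnK", "met": "trnM", "phe": "trnF", "pro": "trnP", "thr": "trnT",
    "trp": "trnW", "tyr": "trnY", "val": "trnV",
}

_DIALECTS: dict[str, str] = {}


def _register(canon: str, *aliases: str) -> None:
    _DIALECTS[canon.lower()] = canon
    for a in aliases:
        _DIALECTS[a.lower()] = canon


_register("cox1", "coi", "co1", "coxi", "cytochrome c oxidase subunit 1", "cytochrome oxidase subunit i", "cytochrome c oxidase subunit i")
_register("cox2", "coii", "co2", "coxii", "cytochrome c oxidase subunit 2", "cytochrome c oxidase subunit ii")
_register("cox3", "coiii", "co3", "coxiii", "cytochrome c oxidase subunit 3", "cytochrome c oxidase subunit iii")
_register("atp6", "atpase6", "atpase 6", "atp synthase f0 subunit 6")
_register("atp8", "atpase8", "atpase 8", "atp synthase f0 subunit 8")
_register("nad1", "nd1", "nadh1", "nadh dehydrogenase subunit 1")
_register("nad2", "nd2", "nadh2", "nadh dehydrogenase subunit 2")
_register("nad3", "nd3", "nadh3", "nadh dehydrogenase subunit 3")
_register("nad4", "nd4", "nadh4", "nadh dehydrogenase subunit 4")
_register("nad4L", "nd4l", "nadh4l", "nadh dehydrogenase subunit 4l")
_register("nad5", "nd5", "nadh5", "nadh dehydrogenase subunit 5")
_register("nad6", "nd6", "nadh6", "nadh dehydrogenase subunit 6")
_register("Cytb", "cytb", "cob", "cyt b", "cytochrome b", "cyb")
_register("rrnL", "16s", "16s rrna", "16s ribosomal rna", "l-rrna", "lrrna", "rrn16", "large subunit ribosomal rna")
_register("rrnS", "12s", "12s rrna", "12s ribosomal rna", "s-rrna", "srrna", "rrn12", "small subunit ribosomal rna")
_register(AT_RICH, "at-rich region", "at rich region", "a+t-rich region", "a+t rich region", "d-loop", "control region", "putative control region")
for _aa, _trn in _AA3_TO_TRN.items():
    _register(_trn, f"trna-{_aa}", f"trn{_trn[3].lower()}", f"trna {_aa}")
_register("trnL1", "trna-leu(cun)", "trnl-cun", "trnl1", "trna-leu (cun)", "trna-leu1")
_register("trnL2", "trna-leu(uur)", "trnl-uur", "trnl2", "trna-leu (uur)", "trna-leu2", "trnl-taa")
_register("trnS1", "trna-ser(agn)", "trns-agn", "trns1", "trna-ser (agn)", "trna-ser1", "trns-gct")
_register("trnS2", "trna-ser(ucn)", "trns-ucn", "trns2", "trna-ser (ucn)", "trna-ser2", "trns-tga")


def normalize_gene_name(raw: str, feature_role: str = "") -> str:
    """Map a heterogeneous gene label to the canonical vocabulary.

    Case-insensitive, deterministic, and idempotent; unmappable labels
    (including tRNA-Leu/tRNA-Ser without an anticodon-family qualifier)
    return the sentinel ``"unknown"`` rather than raising.
    """
    if not raw:
        return ROLE_UNKNOWN
    key = raw.strip().lower()
    key = re.sub(r"\s+", " ", key)
    if key in _DIALECTS:
        return _DIALECTS[key]
    # tRNA labels with embedded codon/anticodon hints, e.g. "tRNA-Leu (UUR)"
    m = re.match(r"^trna?[-_ ]?([a-z]{3})\s*\(?([acgut]{3})?\)?$", key)
    if m:
        aa, codon = m.group(1), m.group(2)
        if aa == "leu":
            if codon in ("cun", "cta", "tag"):
                return "trnL1"
            if codon in ("uur", "tta", "taa"):
                return "trnL2"
            return ROLE_UNKNOWN
        if aa == "ser":
            if codon in ("agn", "aga", "gct", "tct"):
                return "trnS1"
            if codon in ("ucn", "tca", "tga"):
                return "trnS2"
            return ROLE_UNKNOWN
        if aa in _AA3_TO_TRN:
            return _AA3_TO_TRN[aa]
    return ROLE_UNKNOWN


def role_for_name(canonical_name: str) -> str:
    if canonical_name in PCG_NAMES:
        return ROLE_PCG
    if canonical_name in TRNA_NAMES:
        return ROLE_TRNA
    if canonical_name in RRNA_NAMES:
        return ROLE_RRNA
    if canonical_name == AT_RICH:
        return ROLE_CR
    return ROLE_UNKNOWN


# --- sequence extraction -----------------------------------------------------

def extract_feature_sequence(genome: AnnotatedMitogenome, feature: GeneFeature) -> str:
    """Coding-sense sequence of a feature.

    The substring is taken modulo the genome length for wrap-around
    intervals and reverse-complemented for minority-strand (N) features, so
    the result always reads 5'->3' in the gene's own sense and has length
    ``feature.length_bp``.
    """
    L = genome.length_bp
    if feature.length_bp > L:
        raise CoordinateError(f"{feature.canonical_name}: feature longer than genome")
    if feature.end <= L:
        sub = genome.sequence[feature.start:feature.end]
    else:
        if not genome.is_circular:
            raise CoordinateError(f"{feature.canonical_name}: wrap-around feature on a linear genome")
        sub = (genome.sequence + genome.sequence)[feature.start:feature.end]
    return reverse_complement(sub) if feature.strand == "N" else sub


def rotate(genome: AnnotatedMitogenome, offset: int) -> AnnotatedMitogenome:
    """Move the circular origin by ``offset`` bp (feature content preserved)."""
    L = genome.length_bp
    offset %= L
    seq = genome.sequence[offset:] + genome.sequence[:offset]
    feats = []
    for f in genome.features:
        s = (f.start - offset) % L
        feats.append(replace(f, start=s, end=s + f.length_bp))
    return AnnotatedMitogenome(id=genome.id, sequence=seq, features=feats, is_circular=genome.is_circular)


# --- GenBank I/O -------------------------------------------------------------

_GB_TYPE_FOR_ROLE = {
    ROLE_PCG: "CDS",
    ROLE_TRNA: "tRNA",
    ROLE_RRNA: "rRNA",
    ROLE_CR: "D-loop",
    ROLE_UNKNOWN: "misc_feature",
}
_ROLE_FOR_GB_TYPE = {
    "CDS": ROLE_PCG,
    "tRNA": ROLE_TRNA,
    "rRNA": ROLE_RRNA,
    "D-loop": ROLE_CR,
}


def _feature_label(feat: SeqFeature) -> str:
    for key in ("gene", "product", "note", "standard_name"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return ""


def _from_seqfeature(feat: SeqFeature, length: int, record_id: str) -> GeneFeature | None:
    if feat.type in ("source", "gene"):
        return None
    loc = feat.location
    if loc is None:
        raise ParseError(f"{record_id}: feature {feat.type} without location")
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        # origin-spanning join(x..L, 1..y)
        if len(parts) == 2 and int(parts[1].end) == length and int(parts[0].start) == 0:
            start, end = int(parts[1].start), int(parts[0].end) + length
        else:
            start, end = int(parts[0].start), int(parts[-1].end)
    else:
        start, end = int(loc.start), int(loc.end)
    if start < 0 or end > 2 * length or min(start, end) >= length:
        raise CoordinateError(f"{record_id}: feature {feat.type} coordinates [{start},{end}) outside sequence")
    strand = "N" if loc.strand == -1 else "J"
    raw = _feature_label(feat)
    canon = normalize_gene_name(raw)
    role = _ROLE_FOR_GB_TYPE.get(feat.type, ROLE_UNKNOWN)
    if feat.type == "misc_feature" and canon == AT_RICH:
        role = ROLE_CR
    if canon == ROLE_UNKNOWN:
        if role == ROLE_CR:
            canon = AT_RICH
        else:
            logger.warning("%s: unmappable feature name %r (%s) retained with role 'unknown'", record_id, raw, feat.type)
            role = ROLE_UNKNOWN
            canon = ROLE_UNKNOWN
    elif role == ROLE_UNKNOWN:
        role = role_for_name(canon)
    return GeneFeature(canonical_name=canon, role=role, start=start, end=end, strand=strand, raw_name=raw)


def _record_to_genome(record: SeqRecord) -> AnnotatedMitogenome:
    seq = str(record.seq).upper()
    if not seq:
        raise ParseError(f"{record.id}: GenBank record without sequence")
    feats = []
    for feat in record.features:
        gf = _from_seqfeature(feat, len(seq), record.id)
        if gf is not None:
            feats.append(gf)
    if not feats:
        raise ParseError(f"{record.id}: no usable features")
    circular = record.annotations.get("topology", "circular") != "linear"
    return AnnotatedMitogenome(id=record.id.split(".")[0], sequence=seq, features=feats, is_circular=circular)


def read_genbank(path: str | Path) -> AnnotatedMitogenome:
    """Read the first record of a GenBank flat file as an annotated mitogenome."""
    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise ParseError(f"{path}: no GenBank records found")
    if len(records) > 1:
        logger.warning("%s: %d records; using the first", path, len(records))
    return _record_to_genome(records[0])


def iter_genbank(path: str | Path) -> Iterable[AnnotatedMitogenome]:
    for record in SeqIO.parse(str(path), "genbank"):
        yield _record_to_genome(record)


def _to_seqfeature(gf: GeneFeature, length: int) -> SeqFeature:
    strand = -1 if gf.strand == "N" else 1
    if gf.end <= length:
        loc = SimpleLocation(gf.start, gf.end, strand=strand)
    else:
        loc = CompoundLocation(
            [SimpleLocation(gf.start, length, strand=strand), SimpleLocation(0, gf.end - length, strand=strand)]
        )
    quals = {"gene": [gf.canonical_name]}
    return SeqFeature(location=loc, type=_GB_TYPE_FOR_ROLE.get(gf.role, "misc_feature"), qualifiers=quals)


def write_genbank(genome: AnnotatedMitogenome, path: str | Path) -> None:
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id[:16],
        description=f"{genome.id} mitochondrion, complete genome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.is_circular else "linear",
            "data_file_division": "INV",
        },
    )
    record.features = [_to_seqfeature(f, genome.length_bp) for f in genome.features]
    SeqIO.write([record], str(path), "genbank")


# --- FASTA + feature-table sidecar ------------------------------------------

def write_fasta(genome: AnnotatedMitogenome, path: str | Path) -> None:
    record = SeqRecord(Seq(genome.sequence), id=genome.id, description="mitochondrion, complete genome")
    SeqIO.write([record], str(path), "fasta")


def write_feature_table(genome: AnnotatedMitogenome, path: str | Path) -> None:
    """5-column TSV sidecar: name, role, start (1-based), end (1-based incl.), strand."""
    L = genome.length_bp
    with open(path, "w") as fh:
        fh.write("name\trole\tstart_1based\tend_1based\tstrand\n")
        for f in genome.features:
            end1 = f.end if f.end <= L else f.end - L  # wrap: inclusive end past origin
            fh.write(f"{f.canonical_name}\t{f.role}\t{f.start + 1}\t{end1}\t{f.strand}\n")


def read_fasta(fasta_path: str | Path, table_path: str | Path | None = None) -> AnnotatedMitogenome:
    """Read a FASTA genome, optionally annotated by a 5-column TSV sidecar."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ParseError(f"{fasta_path}: no FASTA records found")
    record = records[0]
    seq = str(record.seq).upper()
    feats: list[GeneFeature] = []
    if table_path is not None:
        feats = _read_feature_table(table_path, len(seq))
    return AnnotatedMitogenome(id=record.id.split(".")[0], sequence=seq, features=feats)


def _read_feature_table(path: str | Path, length: int) -> list[GeneFeature]:
    feats = []
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("name"):
            raise ParseError(f"{path}: missing feature-table header")
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise ParseError(f"{path}:{line_no}: expected 5 tab-separated columns")
            name, role, s1, e1, strand = parts
            start = int(s1) - 1
            end = int(e1)
            if end <= start:  # wrap-around, inclusive end before start
                end += length
            canon = normalize_gene_name(name)
            if canon == ROLE_UNKNOWN and role == ROLE_CR:
                canon = AT_RICH
            feats.append(GeneFeature(canonical_name=canon, role=role, start=start, end=end, strand=strand))
    return feats


def load_genomes(paths: Sequence[str | Path]) -> list[AnnotatedMitogenome]:
    """Load a mixed list of GenBank/FASTA paths (FASTA requires a .tsv sidecar)."""
    genomes = []
    for p in paths:
        p = Path(p)
        if p.suffix.lower() in (".gb", ".gbk", ".genbank", ".gbff"):
            genomes.append(read_genbank(p))
        else:
            sidecar = p.with_suffix(".tsv")
            genomes.append(read_fasta(p, sidecar if sidecar.exists() else None))
    return genomes
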