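"""Generator of annotated circular mitogenomes with known ground truth.

The generator realizes a structural plan — gene order and strands, per-gene
lengths, start/stop codons, engineered overlaps and intergenic spacers, and
control-region elements (ATAGA + poly-T origin, (AT)n repeats, an
ATTTA-anchored microsatellite) — on top of i.i.d. base draws tuned to a
target A+T content. Protein-coding genes are built codon-by-codon with
rejection of internal stop codons under the invertebrate mitochondrial
code; because rejection removes A/T-rich codons (TAA, TAG), the PCG draw
probabilities are recalibrated so the conditional composition still hits
the target in expectation. Every structural decision is recorded in a
machine-readable ground-truth sidecar sufficient to verify downstream
modules exactly.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from mitochar.codon_profile import STOP_CODONS
from mitochar.errors import InfeasiblePlanError
from mitochar.gene_layout import LEPIDOPTERAN_GENE_ORDER
from mitochar.genome_io import (
    AT_RICH,
    PCG_NAMES,
    ROLE_CR,
    TRNA_NAMES,
    AnnotatedMitogenome,
    GeneFeature,
    role_for_name,
)
from mitochar import study

_COMPL = {"A": "T", "T": "A", "G": "C", "C": "G"}

DEFAULT_PCG_LENGTHS = {
    "cox1": 1537, "cox2": 688, "atp8": 162, "atp6": 678, "cox3": 786,
    "nad2": 1002, "nad3": 354, "nad4": 1339, "nad4L": 291, "nad5": 1743,
    "nad6": 531, "Cytb": 1149, "nad1": 939,
}
DEFAULT_STOPS = {"cox1": "T-", "cox2": "T-", "nad4": "T-"}
DEFAULT_OVERLAPS = {("trnW", "trnC"): 8, ("atp8", "atp6"): 7, ("trnL1", "rrnL"): 21}
DEFAULT_SPACERS = {("trnQ", "nad2"): 91, ("trnP", "nad6"): 2, ("trnS2", "nad1"): 17, ("nad1", "trnL1"): 1}


@dataclass
class CrPlan:
    """Control-region content plan; ``length=None`` lets the CR absorb the
    genome-length residual."""

    length: int | None = None
    poly_t_length: int = 20
    at_repeats: tuple[int, ...] = (4, 6)
    microsat_unit: str = "TA"
    microsat_copies: int = 5
    at_content: float | None = None  # percent; None -> genome-wide target


@dataclass
class GeneratorConfig:
    seed: int = 0
    genome_id: str = "synthetic"
    genome_length_target: int = 15300
    at_content_target: float = 80.0
    at_ratio: float = 0.5  # share of A within A+T (J strand)
    gc_ratio: float = 0.5  # share of G within G+C (J strand)
    gene_order: tuple[tuple[str, str], ...] = LEPIDOPTERAN_GENE_ORDER
    pcg_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_PCG_LENGTHS))
    trna_lengths: dict[str, int] = field(default_factory=lambda: {t: 66 for t in TRNA_NAMES} | {"trnS1": 61})
    rrna_lengths: dict[str, int] = field(default_factory=lambda: {"rrnL": 1385, "rrnS": 785})
    start_codons: dict[str, str] = field(default_factory=lambda: {"cox1": "CGA"})
    default_start: str = "ATG"
    stop_codons: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_STOPS))
    default_stop: str = "TAA"
    overlaps: dict[tuple[str, str], int] = field(default_factory=lambda: dict(DEFAULT_OVERLAPS))
    spacers: dict[tuple[str, str], int] = field(default_factory=lambda: dict(DEFAULT_SPACERS))
    cr: CrPlan = field(default_factory=CrPlan)
    pcg_at: float | None = None
    trna_at: float | None = None
    rrna_at: float | None = None
    spacer_at: float | None = None
    # probability that a free PCG codon is emitted directly as TTA (Leu2),
    # emulating the strong UUA preference of AT-biased mitogenomes; folded
    # into the composition calibration so the A+T target is still met
    tta_enrichment: float = 0.1


@dataclass
class GroundTruth:
    """Realized structural facts of a generated genome."""

    genome_id: str
    genome_length: int
    at_content_target: float
    features: dict[str, dict]  # name -> {start, end, strand, length}
    start_codons: dict[str, str]
    stop_codons: dict[str, str]
    overlaps: list[tuple[str, str, int]]
    spacers: list[tuple[str, str, int]]
    cr_interval: tuple[int, int]
    cr_elements: dict  # CR-relative coordinates of planted elements

    def as_dict(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "genome_length": self.genome_length,
            "at_content_target": self.at_content_target,
            "features": self.features,
            "start_codons": self.start_codons,
            "stop_codons": self.stop_codons,
            "overlaps": [list(o) for o in self.overlaps],
            "spacers": [list(s) for s in self.spacers],
            "cr_interval": list(self.cr_interval),
            "cr_elements": self.cr_elements,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=1, sort_keys=True))


# --- composition helpers -----------------------------------------------------

def _class_probs(at_pct: float, at_ratio: float, gc_ratio: float) -> dict[str, float]:
    at = at_pct / 100.0
    return {
        "A": at * at_ratio,
        "T": at * (1 - at_ratio),
        "G": (1 - at) * gc_ratio,
        "C": (1 - at) * (1 - gc_ratio),
    }


def _coding_probs(j_probs: dict[str, float], strand: str) -> dict[str, float]:
    if strand == "J":
        return dict(j_probs)
    return {b: j_probs[_COMPL[b]] for b in "ATGC"}


def _no_stop_marginal(p: dict[str, float]) -> dict[str, float]:
    """Per-base marginal of i.i.d. codons conditional on not being TAA/TAG."""
    num = {b: 0.0 for b in "ATGC"}
    den = 0.0
    for a in "ATGC":
        for b in "ATGC":
            for c in "ATGC":
                if a + b + c in STOP_CODONS:
                    continue
                w = p[a] * p[b] * p[c]
                den += w
                for x in (a, b, c):
                    num[x] += w
    return {b: num[b] / (3.0 * den) for b in "ATGC"}


def _calibrate_pcg_probs(target: dict[str, float]) -> dict[str, float]:
    """Draw probabilities whose stop-rejected codon stream has per-base
    marginal ``target`` (iterative proportional fitting on the 62 non-stop
    codons; rejection of the A/T-rich stops TAA/TAG otherwise skews both the
    A+T level and the A:T balance)."""
    p = dict(target)
    for _ in range(60):
        m = _no_stop_marginal(p)
        p = {b: p[b] * target[b] / m[b] if m[b] > 0 else 0.0 for b in "ATGC"}
        z = sum(p.values())
        p = {b: v / z for b, v in p.items()}
    return p


def _draw(rng: random.Random, probs: dict[str, float]) -> str:
    return rng.choices("ATGC", weights=[probs[b] for b in "ATGC"])[0]


# --- plan validation and coordinate layout -----------------------------------

def _junctions(order: tuple[tuple[str, str], ...]) -> list[tuple[str, str]]:
    names = [n for n, _ in order]
    return [(names[i], names[(i + 1) % len(names)]) for i in range(len(names))]


def _validate(cfg: GeneratorConfig, gene_lengths: dict[str, int]) -> None:
    names = [n for n, _ in cfg.gene_order]
    junctions = set(_junctions(cfg.gene_order))
    for pair in list(cfg.overlaps) + list(cfg.spacers):
        if pair not in junctions:
            raise InfeasiblePlanError(f"pair {pair} is not consecutive in the gene order")
    for pair, bp in cfg.overlaps.items():
        limit = min(gene_lengths.get(pair[0], 10**9), gene_lengths.get(pair[1], 10**9))
        if bp <= 0 or bp >= limit:
            raise InfeasiblePlanError(f"overlap {pair} of {bp} bp not shorter than both partners")
    for gene in PCG_NAMES:
        if gene not in names:
            continue
        length = gene_lengths[gene]
        stop = cfg.stop_codons.get(gene, cfg.default_stop)
        rem = {"T-": 1, "TA-": 2}.get(stop, 0)
        if stop not in ("TAA", "TAG", "T-", "TA-"):
            raise InfeasiblePlanError(f"{gene}: unsupported stop {stop}")
        if length % 3 != rem:
            raise InfeasiblePlanError(
                f"{gene}: length {length} mod 3 = {length % 3} incompatible with stop {stop}"
            )
        if length < 60:
            raise InfeasiblePlanError(f"{gene}: PCG length {length} < 60")
        start = cfg.start_codons.get(gene, cfg.default_start)
        if len(start) != 3 or any(b not in "ATGC" for b in start):
            raise InfeasiblePlanError(f"{gene}: bad start codon {start}")


def _cr_layout(plan: CrPlan, cr_len: int) -> tuple[dict, list[tuple[int, str]]]:
    """Place planted elements inside the CR; returns (ground truth, pins).

    Pins are (CR-relative position, base). Guard bases (C/G) flank runs so
    each planted element is maximal and recovered at exact coordinates.
    """
    pins: list[tuple[int, str]] = []
    truth: dict = {}
    pos = 3
    # origin: ATAGA + poly-T + guard
    motif = "ATAGA" + "T" * plan.poly_t_length
    for i, b in enumerate(motif):
        pins.append((pos + i, b))
    pins.append((pos + len(motif), "G"))
    truth["origin_motif"] = {"position": pos, "poly_t_length": plan.poly_t_length}
    pos += len(motif) + 1 + 4
    # (AT)n runs, C-guarded on both sides
    truth["at_repeats"] = []
    for n in plan.at_repeats:
        pins.append((pos, "C"))
        run = "AT" * n
        for i, b in enumerate(run):
            pins.append((pos + 1 + i, b))
        pins.append((pos + 1 + len(run), "C"))
        truth["at_repeats"].append({"position": pos + 1, "copies": n})
        pos += len(run) + 2 + 4
    # ATTTA anchor + microsatellite + guard
    anchor = "ATTTA"
    ms = plan.microsat_unit * plan.microsat_copies
    pins.append((pos - 1, "C"))  # keep the anchor's A out of upstream runs
    for i, b in enumerate(anchor + ms):
        pins.append((pos + i, b))
    pins.append((pos + len(anchor) + len(ms), "G"))
    truth["microsatellite"] = {
        "anchor_position": pos,
        "position": pos + len(anchor),
        "unit": plan.microsat_unit,
        "copies": plan.microsat_copies,
    }
    pos += len(anchor) + len(ms) + 1
    if pos + 2 > cr_len:
        raise InfeasiblePlanError(
            f"control region of {cr_len} bp cannot hold planted elements ({pos + 2} bp needed)"
        )
    return truth, pins


def _distribute_residual(
    residual: int,
    order: tuple[tuple[str, str], ...],
    taken: set[tuple[str, str]],
    chunk: int = 20,
) -> dict[tuple[str, str], int]:
    """Spread a length residual over unconstrained junctions as small spacers."""
    extra: dict[tuple[str, str], int] = {}
    free = [j for j in _junctions(order) if j not in taken and AT_RICH not in j]
    if residual < 0:
        raise InfeasiblePlanError(f"plan exceeds genome length target by {-residual} bp")
    i = 0
    while residual > 0:
        if i >= len(free):
            raise InfeasiblePlanError("not enough junctions to absorb the length residual")
        take = min(chunk, residual)
        extra[free[i]] = take
        residual -= take
        i += 1
    return extra


# --- main entry --------------------------------------------------------------

def generate(config: GeneratorConfig | None = None) -> tuple[AnnotatedMitogenome, GroundTruth]:
    """Generate one annotated circular mitogenome plus its ground truth.

    Deterministic under ``config.seed``. PCGs begin with their planned start
    codon, end with TAA/TAG or a pinned incomplete tail, and contain no
    internal stops under the invertebrate mitochondrial code; control-region
    elements are planted verbatim with guard bases so scanners recover them
    at exact coordinates.
    """
    cfg = config or GeneratorConfig()
    rng = random.Random(cfg.seed)
    L = cfg.genome_length_target

    gene_lengths: dict[str, int] = {}
    for name, _ in cfg.gene_order:
        if name in PCG_NAMES:
            gene_lengths[name] = cfg.pcg_lengths[name]
        elif name in TRNA_NAMES:
            gene_lengths[name] = cfg.trna_lengths[name]
        elif name in ("rrnL", "rrnS"):
            gene_lengths[name] = cfg.rrna_lengths[name]
    _validate(cfg, gene_lengths)

    spacers = dict(cfg.spacers)
    non_cr_total = sum(gene_lengths.values())
    fixed_gaps = sum(spacers.values()) - sum(cfg.overlaps.values())
    if cfg.cr.length is None:
        cr_len = L - non_cr_total - fixed_gaps
        if cr_len < 40:
            raise InfeasiblePlanError(f"residual control region of {cr_len} bp is infeasible")
    else:
        cr_len = cfg.cr.length
        residual = L - non_cr_total - cr_len - fixed_gaps
        taken = set(cfg.overlaps) | set(spacers)
        spacers.update(_distribute_residual(residual, cfg.gene_order, taken))
    gene_lengths[AT_RICH] = cr_len

    # coordinates: walk the circle from position 0
    features: list[GeneFeature] = []
    pos = 0
    order_names = [n for n, _ in cfg.gene_order]
    strand_of = dict(cfg.gene_order)
    for i, name in enumerate(order_names):
        length = gene_lengths[name]
        features.append(
            GeneFeature(
                canonical_name=name,
                role=role_for_name(name) if name != AT_RICH else ROLE_CR,
                start=pos,
                end=pos + length,
                strand=strand_of[name],
            )
        )
        nxt = (name, order_names[(i + 1) % len(order_names)])
        pos = pos + length - cfg.overlaps.get(nxt, 0) + spacers.get(nxt, 0)
    if pos != L:
        raise InfeasiblePlanError(f"layout closes at {pos} bp, target {L} bp")

    # pinned bases on the J strand
    grid: list[str | None] = [None] * L

    def pin(gpos: int, base: str, strand: str) -> None:
        gpos %= L
        b = base if strand == "J" else _COMPL[base]
        if grid[gpos] is not None and grid[gpos] != b:
            raise InfeasiblePlanError(f"conflicting pinned bases at position {gpos}")
        grid[gpos] = b

    def coding_to_genome(feat: GeneFeature, k: int) -> int:
        return (feat.start + k) % L if feat.strand == "J" else (feat.end - 1 - k) % L

    feat_of = {f.canonical_name: f for f in features}
    truth_starts: dict[str, str] = {}
    truth_stops: dict[str, str] = {}
    for name in order_names:
        if name not in PCG_NAMES:
            continue
        feat = feat_of[name]
        start = cfg.start_codons.get(name, cfg.default_start)
        stop = cfg.stop_codons.get(name, cfg.default_stop)
        for k, b in enumerate(start):
            pin(coding_to_genome(feat, k), b, feat.strand)
        tail = {"T-": "T", "TA-": "TA"}.get(stop, stop)
        for k, b in enumerate(tail):
            pin(coding_to_genome(feat, feat.length_bp - len(tail) + k), b, feat.strand)
        truth_starts[name] = start
        truth_stops[name] = stop

    cr_feat = feat_of[AT_RICH]
    cr_truth, cr_pins = _cr_layout(cfg.cr, cr_len)
    for rel, b in cr_pins:
        pin(coding_to_genome(cr_feat, rel), b, cr_feat.strand)

    # fill: PCGs codon-wise with stop rejection, everything else i.i.d.
    at = cfg.at_content_target
    j_probs = {
        "PCG": _class_probs(cfg.pcg_at if cfg.pcg_at is not None else at, cfg.at_ratio, cfg.gc_ratio),
        "tRNA": _class_probs(cfg.trna_at if cfg.trna_at is not None else at, cfg.at_ratio, cfg.gc_ratio),
        "rRNA": _class_probs(cfg.rrna_at if cfg.rrna_at is not None else at, cfg.at_ratio, cfg.gc_ratio),
        "control-region": _class_probs(cfg.cr.at_content if cfg.cr.at_content is not None else at,
                                       cfg.at_ratio, cfg.gc_ratio),
        "spacer": _class_probs(cfg.spacer_at if cfg.spacer_at is not None else at,
                               cfg.at_ratio, cfg.gc_ratio),
    }
    pcg_cal_cache: dict[str, dict[str, float]] = {}

    for feat in features:
        if feat.role == "PCG":
            if feat.strand not in pcg_cal_cache:
                # desired coding-sense per-base marginal for this strand, with
                # the TTA enrichment's contribution (A:1/3, T:2/3) folded out
                # of the i.i.d. share so the class composition is still met
                q = _coding_probs(j_probs["PCG"], feat.strand)
                lam = cfg.tta_enrichment
                tta = {"A": 1 / 3, "T": 2 / 3, "G": 0.0, "C": 0.0}
                iid_q = {b: (q[b] - lam * tta[b]) / (1.0 - lam) for b in "ATGC"}
                if min(iid_q.values()) < 0:
                    raise InfeasiblePlanError("tta_enrichment incompatible with the PCG composition target")
                pcg_cal_cache[feat.strand] = _calibrate_pcg_probs(iid_q)
            probs = pcg_cal_cache[feat.strand]
            n_codons = feat.length_bp // 3
            for ci in range(n_codons):
                gpos = [coding_to_genome(feat, 3 * ci + k) for k in range(3)]
                fixed = [
                    (grid[g] if feat.strand == "J" else (_COMPL[grid[g]] if grid[g] else None))
                    for g in gpos
                ]
                if all(b is not None for b in fixed):
                    continue
                if all(b is None for b in fixed) and rng.random() < cfg.tta_enrichment:
                    for g, b in zip(gpos, "TTA"):
                        grid[g] = b if feat.strand == "J" else _COMPL[b]
                    continue
                for _try in range(200):
                    codon = "".join(b if b is not None else _draw(rng, probs) for b in fixed)
                    if codon not in STOP_CODONS:
                        break
                else:
                    raise InfeasiblePlanError(f"{feat.canonical_name}: cannot avoid stop codon {ci}")
                for g, b in zip(gpos, codon):
                    grid[g] = b if feat.strand == "J" else _COMPL[b]
            # incomplete tails beyond the last full codon are already pinned
        elif feat.role == ROLE_CR:
            # condition the filler on the planted bases so the whole region
            # still hits its A+T target in expectation
            positions = [(feat.start + k) % L for k in range(feat.length_bp)]
            pinned_at = sum(1 for g in positions if grid[g] in ("A", "T"))
            free = [g for g in positions if grid[g] is None]
            cr_at_target = (cfg.cr.at_content if cfg.cr.at_content is not None else at) / 100.0
            want = cr_at_target * feat.length_bp - pinned_at
            frac = min(1.0, max(0.0, want / len(free))) if free else 0.0
            probs = _class_probs(100.0 * frac, cfg.at_ratio, cfg.gc_ratio)
            for g in free:
                grid[g] = _draw(rng, probs)
        else:
            key = feat.role if feat.role in j_probs else "spacer"
            probs = j_probs[key]
            for k in range(feat.length_bp):
                g = (feat.start + k) % L
                if grid[g] is None:
                    grid[g] = _draw(rng, probs)

    sp_probs = j_probs["spacer"]
    for g in range(L):
        if grid[g] is None:
            grid[g] = _draw(rng, sp_probs)

    genome = AnnotatedMitogenome(id=cfg.genome_id, sequence="".join(grid), features=features)

    realized_overlaps = []
    realized_spacers = []
    for i, name in enumerate(order_names):
        nxt = order_names[(i + 1) % len(order_names)]
        if (name, nxt) in cfg.overlaps:
            realized_overlaps.append((name, nxt, cfg.overlaps[(name, nxt)]))
        if (name, nxt) in spacers:
            realized_spacers.append((name, nxt, spacers[(name, nxt)]))
    truth = GroundTruth(
        genome_id=cfg.genome_id,
        genome_length=L,
        at_content_target=at,
        features={
            f.canonical_name: {"start": f.start, "end": f.end, "strand": f.strand, "length": f.length_bp}
            for f in features
        },
        start_codons=truth_starts,
        stop_codons=truth_stops,
        overlaps=realized_overlaps,
        spacers=realized_spacers,
        cr_interval=(cr_feat.start, cr_feat.end),
        cr_elements=cr_truth,
    )
    return genome, truth


# --- study-like fixtures ------------------------------------------------------

def study_like_fixture_set(seed: int = 0) -> list[tuple[AnnotatedMitogenome, GroundTruth]]:
    """Five genomes emulating the printed per-species targets of the study set.

    Lengths are exact (15,340/15,295/15,304/15,295/15,289 bp in accession
    order MZ502493/91/92/90/89); whole-genome and per-class compositions,
    PCG/tRNA/rRNA totals, shared overlaps and spacers, control-region sizes
    and planted elements follow the printed comparative tables.
    """
    out = []
    for i, acc in enumerate(study.ACCESSIONS):
        cfg = fixture_config(acc, seed=seed * len(study.ACCESSIONS) + i)
        out.append(generate(cfg))
    return out


def fixture_config(acc: str, seed: int = 0) -> GeneratorConfig:
    printed = study.PRINTED[acc]
    plan = study.FIXTURE_PLANS[acc]
    at_whole = printed["pct_A"] + printed["pct_T"]
    gc_whole = printed["pct_G"] + printed["pct_C"]
    trna_lengths = study.fixture_trna_lengths(acc)
    pcg_lengths = study.fixture_pcg_lengths(acc)
    rrna_lengths = {"rrnL": plan["rrnL"], "rrnS": plan["rrnS"]}
    L = printed["genome_length"]
    cr_len = plan["cr_length"]
    trna_at = 81.5
    rrna_at = plan["rna_at"]
    cr_at = study.MEAN_CR_AT_CONTENT
    # exclusive coverage: overlap bases are written by the upstream partner
    pcg_excl = sum(pcg_lengths.values()) - 7
    trna_excl = sum(trna_lengths.values()) - 8
    rrna_excl = sum(rrna_lengths.values()) - 21
    spacer_total = L - (pcg_excl + trna_excl + rrna_excl + cr_len)
    pcg_at = (
        at_whole * L - trna_at * trna_excl - rrna_at * rrna_excl - cr_at * cr_len - at_whole * spacer_total
    ) / pcg_excl
    spacers = dict(DEFAULT_SPACERS)
    spacers[("trnQ", "nad2")] = plan["trnq_nad2_spacer"]
    return GeneratorConfig(
        seed=seed,
        genome_id=acc,
        genome_length_target=L,
        at_content_target=at_whole,
        at_ratio=printed["pct_A"] / at_whole,
        gc_ratio=printed["pct_G"] / gc_whole,
        pcg_lengths=pcg_lengths,
        trna_lengths=trna_lengths,
        rrna_lengths=rrna_lengths,
        start_codons={"cox1": plan["cox1_start"]},
        stop_codons=study.fixture_pcg_stops(acc),
        spacers=spacers,
        cr=CrPlan(
            length=cr_len,
            poly_t_length=plan["poly_t"],
            at_repeats=tuple(plan["at_repeats"]),
            at_content=cr_at,
        ),
        pcg_at=pcg_at,
        trna_at=trna_at,
        rrna_at=rrna_at,
        spacer_at=at_whole,
    )


def write_fixture_files(out_dir: str | Path, seed: int = 0) -> list[Path]:
    """Emit the five study-like fixtures as GenBank + FASTA + TSV + ground truth."""
    from mitochar.genome_io import write_fasta, write_feature_table, write_genbank

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for genome, truth in study_like_fixture_set(seed):
        gb = out_dir / f"{genome.id}.gb"
        write_genbank(genome, gb)
        write_fasta(genome, out_dir / f"{genome.id}.fasta")
        write_feature_table(genome, out_dir / f"{genome.id}.tsv")
        truth.write_json(out_dir / f"{genome.id}.truth.json")
        paths.append(gb)
    return paths
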