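"""Circular gene-layout arithmetic: order signature, overlaps, spacers.

Consecutive features on the circle (sorted by start, plus the wrap pair)
either overlap (negative gap), leave an intergenic spacer (positive gap) or
abut exactly. The conservation identity

    sum(feature lengths) - sum(overlaps) + sum(spacers) == genome length

holds whenever no feature is nested inside another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from mitochar.genome_io import AnnotatedMitogenome, ROLE_CR

logger = logging.getLogger(__name__)

# Gene order of the derived lepidopteran mitogenome: the ancestral insect
# arrangement with trnM translocated in front of trnI-trnQ, the order shared
# by ditrysian Lepidoptera. Tuples are (canonical name, strand).
LEPIDOPTERAN_GENE_ORDER: tuple[tuple[str, str], ...] = (
    ("trnM", "J"), ("trnI", "J"), ("trnQ", "N"), ("nad2", "J"), ("trnW", "J"),
    ("trnC", "N"), ("trnY", "N"), ("cox1", "J"), ("trnL2", "J"), ("cox2", "J"),
    ("trnK", "J"), ("trnD", "J"), ("atp8", "J"), ("atp6", "J"), ("cox3", "J"),
    ("trnG", "J"), ("nad3", "J"), ("trnA", "J"), ("trnR", "J"), ("trnN", "J"),
    ("trnS1", "J"), ("trnE", "J"), ("trnF", "N"), ("nad5", "N"), ("trnH", "N"),
    ("nad4", "N"), ("nad4L", "N"), ("trnT", "J"), ("trnP", "N"), ("nad6", "J"),
    ("Cytb", "J"), ("trnS2", "J"), ("nad1", "N"), ("trnL1", "N"), ("rrnL", "N"),
    ("trnV", "N"), ("rrnS", "N"), ("AT-rich", "J"),
)

Junction = tuple[str, str, int]  # (upstream gene, downstream gene, length bp)


@dataclass
class LayoutReport:
    """Overlaps, spacers and abutments between consecutive features on the circle."""

    genome_id: str
    genome_length: int
    order_signature: list[tuple[str, str]]
    overlaps: list[Junction] = field(default_factory=list)
    spacers: list[Junction] = field(default_factory=list)
    abutting: list[tuple[str, str]] = field(default_factory=list)
    nested: list[tuple[str, str]] = field(default_factory=list)

    @property
    def longest_overlap(self) -> Junction | None:
        return max(self.overlaps, key=lambda j: j[2], default=None)

    @property
    def longest_spacer(self) -> Junction | None:
        return max(self.spacers, key=lambda j: j[2], default=None)

    def spacers_excluding_cr(self) -> list[Junction]:
        """Spacers with control-region junctions removed (the alternative tally)."""
        return [j for j in self.spacers if "AT-rich" not in (j[0], j[1])]

    @property
    def total_feature_length(self) -> int:
        return self._total_feature_length

    def conservation_holds(self) -> bool:
        """sum(len) - sum(overlap) + sum(spacer) == genome length (no nesting)."""
        if self.nested:
            return False
        lhs = self._total_feature_length - sum(j[2] for j in self.overlaps) + sum(j[2] for j in self.spacers)
        return lhs == self.genome_length

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for a, b, n in self.overlaps:
            rows.append({"genome": self.genome_id, "upstream": a, "downstream": b, "type": "overlap", "length_bp": n})
        for a, b, n in self.spacers:
            rows.append({"genome": self.genome_id, "upstream": a, "downstream": b, "type": "spacer", "length_bp": n})
        for a, b in self.abutting:
            rows.append({"genome": self.genome_id, "upstream": a, "downstream": b, "type": "abutting", "length_bp": 0})
        return pd.DataFrame(rows)


def layout(genome: AnnotatedMitogenome) -> LayoutReport:
    """Classify every consecutive-pair junction of a circular genome.

    Features are sorted by start; the gap between a feature and its
    successor (including the wrap pair back to the first feature) is a
    spacer when positive, an overlap when negative, abutting at zero.
    Strand is ignored for pairing: overlaps may span strands (trnW/trnC).
    A feature fully nested in its predecessor is reported as a warning and
    its junction is skipped.
    """
    if len(genome.features) < 2:
        raise ValueError(f"{genome.id}: layout needs at least two features")
    feats = sorted(genome.features, key=lambda f: (f.start, f.end))
    L = genome.length_bp
    report = LayoutReport(
        genome_id=genome.id,
        genome_length=L,
        order_signature=[(f.canonical_name, f.strand) for f in feats],
    )
    report._total_feature_length = sum(f.length_bp for f in feats)
    n = len(feats)
    for i, cur in enumerate(feats):
        nxt = feats[(i + 1) % n]
        gap = nxt.start - cur.end
        if i == n - 1:
            gap += L
        if gap < -min(cur.length_bp, nxt.length_bp) or (i < n - 1 and nxt.end <= cur.end):
            logger.warning("%s: %s nested within %s; junction skipped", genome.id, nxt.canonical_name, cur.canonical_name)
            report.nested.append((cur.canonical_name, nxt.canonical_name))
            continue
        pair = (cur.canonical_name, nxt.canonical_name)
        if gap < 0:
            report.overlaps.append((*pair, -gap))
        elif gap > 0:
            report.spacers.append((*pair, gap))
        else:
            report.abutting.append(pair)
    return report


def _rotations(names: list) -> list[list]:
    return [names[i:] + names[:i] for i in range(len(names))]


def gene_order_check(
    genome: AnnotatedMitogenome,
    reference_order: tuple[tuple[str, str], ...] = LEPIDOPTERAN_GENE_ORDER,
) -> tuple[bool, str | None, list[str]]:
    """Rotation-invariant comparison of gene order and strand to a reference.

    Returns (matches, first divergent gene name or None, missing genes).
    Genes absent from the genome are dropped from the reference before
    comparison, so the check proceeds on the intersection.
    """
    observed = [(f.canonical_name, f.strand) for f in sorted(genome.features, key=lambda f: f.start)]
    observed_names = {n for n, _ in observed}
    ref = [(n, s) for n, s in reference_order if n in observed_names]
    ref_names = {n for n, _ in ref}
    observed = [(n, s) for n, s in observed if n in ref_names]
    missing = [n for n, _ in reference_order if n not in observed_names]
    if not ref:
        return False, None, missing
    for rotation in _rotations(observed):
        if rotation == ref:
            return True, None, missing
    # best rotation: anchor on the reference's first gene, report first mismatch
    anchor = ref[0]
    divergence = None
    for rotation in _rotations(observed):
        if rotation[0][0] == anchor[0]:
            for (obs, exp) in zip(rotation, ref):
                if obs != exp:
                    divergence = exp[0]
                    break
            break
    if divergence is None:
        divergence = ref[0][0]
    return False, divergence, missing
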