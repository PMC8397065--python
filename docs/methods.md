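# Methods

## Scope and model

The package treats an annotated circular mitogenome as a majority-strand
(J-strand) sequence plus an ordered list of features in 0-based half-open
coordinates; a feature spanning the origin is stored with `end > length`
and read modulo the genome length, which keeps every interval contiguous
for circular arithmetic. GenBank I/O converts to and from the flat file's
1-based inclusive convention (origin-spanning features become a two-part
`join`). Gene labels are normalized into a canonical 37-gene vocabulary
(cox1–3, atp6/8, nad1–6, nad4L, Cytb; 22 tRNAs with the Leu1/Leu2 and
Ser1/Ser2 disambiguation; rrnL/rrnS; AT-rich region); a tRNA-Leu or
tRNA-Ser without an anticodon-family qualifier is deliberately left
`unknown` rather than guessed. Ambiguity codes other than N are rejected at
parse time; N is carried but excluded from every composition denominator.

## Composition and skews

AT-skew = (A − T)/(A + T) and GC-skew = (G − C)/(G + C). Genome-level rows
are computed on the J strand; gene-class rows (PCGs, tRNAs, rRNAs) on
coding-sense sequence, which reproduces the conventional sign pattern
(negative AT-skew, positive GC-skew for the pooled PCGs). Codon-position
rows drop each gene's trailing incomplete codon so positions 1–3 tile
complete codons exactly; the three position rows and the PCG row then
satisfy an exact integer count identity, which is tested. Report rounding
is 1 decimal for percentages and 4 for skews, applied only at
serialization.

## Codon accounting

Translation uses the invertebrate mitochondrial code (ATA Met, TGA Trp,
AGA/AGG Ser; stops TAA/TAG only), implemented as an explicit 64-codon
table; the test suite cross-checks it against an independent library
implementation. Stop classification follows the length-remainder rule: a
gene of length ≡ 1 (mod 3) ends in the incomplete stop T-, ≡ 2 in TA-,
both completed to TAA by post-transcriptional polyadenylation; a
remainder-0 gene must end TAA/TAG or is flagged. cox1-style CGA starts are
accepted with an `alternative-start` flag; any other non-ATN start warns
but never raises, so novel genomes can be profiled. RSCU is computed on
pooled complete codons of all PCGs (terminal complete stops excluded from
the synonymous families), with leucine split into Leu1 (CTN) and Leu2
(TTA/TTG) and serine into Ser1 (AGN, four-fold under this code) and Ser2
(TCN). Within every used family the RSCU values sum to the family size, an
exact rational identity before rounding.

## Layout arithmetic

Only consecutive features on the circle form junctions (including the wrap
pair), matching how mitogenome papers tabulate overlaps and spacers;
distant accidental intersections are ignored. Negative gap → overlap,
positive → spacer, zero → abutting; strand is ignored for pairing, so
cross-strand overlaps such as trnW–trnC count. The conservation identity
Σ len − Σ overlap + Σ spacer = L holds exactly whenever no feature is
nested in another; nesting produces a warning and skips that junction
rather than corrupting the identity silently. Because published spacer
counts do not state whether control-region junctions are included, the
report exposes both tallies (`spacers` and `spacers_excluding_cr`). The
gene-order check is rotation-invariant and compares name and strand
against the shipped lepidopteran reference order (the ancestral insect
arrangement with trnM translocated ahead of trnI–trnQ — required for the
diagnostic trnQ–nad2 spacer and the rrnS–CR–trnM junctions to be
consecutive pairs at all).

## Control-region scanners

All scanners are exact-match: at control-region scale (≤ a few hundred bp,
hard-capped at 10 kb) exhaustive search is tractable, fully deterministic
and oracle-testable, so no mismatch/indel-tolerant alignment is attempted.
The origin element is ATAGA plus the maximal run of T immediately 3' of it
(zero interruptions allowed — "followed by" is read as adjacency); among
several ATAGA occurrences the longest trailing poly-T wins, ties to the
first. Dinucleotide repeats are maximal strictly alternating A/T blocks
reported under the canonical unit AT with ⌊block/2⌋ copies; the default
threshold is 4 copies, the smallest value reported for these genomes, and
is configurable. The tandem scanner finds, for every unit length u ≤ 6
(configurable to 50), maximal perfect runs via the self-match profile
s[i] = s[i+u], reports a run once at its smallest primitive unit, and
drops runs contained in a longer run of smaller period. Microsatellite
reporting anchors on ATTTA and keeps tandem runs starting within a 10-bp
downstream window; the window size is a documented tunable with no
published value.

## Supermatrix construction

Three dataset modes: PCG (13 blocks), PRT (37 blocks), 12PRT (PRT with
third codon positions struck from PCG blocks, keeping columns ≡ 1,2 mod 3).
PCG blocks are harvested with terminal complete stops and incomplete tails
trimmed, so every PCG block enters frame 0 and is divisible by 3; the
12PRT length identity (12PRT = PRT − Σ block/3) is exact and tested. Block
order is the canonical genome gene order, never alphabetical; taxon order
is input order and identical across the FASTA/relaxed-PHYLIP/NEXUS
writers, which round-trip bit-exactly. Alignment and trimming are
deliberately out of scope (they belong to dedicated external tools);
ragged blocks raise unless the caller explicitly opts into trailing-gap
padding, which flags the result `aligned=False`.

## Synthetic-genome generator

The generator realizes a structural plan — gene order/strands, per-gene
lengths, start/stop codons, an overlap plan (defaults: trnW–trnC 8 bp,
atp8–atp6 7 bp, trnL1–rrnL 21 bp), a spacer plan (large trnQ–nad2 spacer
plus the three shared small spacers), and a control-region plan (ATAGA +
poly-T, a set of (AT)n runs, an ATTTA-anchored microsatellite) — and fills
free positions with i.i.d. draws per region class. Plans are validated
(pairs must be consecutive, overlaps shorter than both partners, stop type
consistent with length mod 3) and geometric closure is exact: with an
unpinned control region the CR absorbs the length residual; with a pinned
CR length the residual is spread over unconstrained junctions as ≤ 20-bp
spacers, keeping the planned longest spacer longest.

PCGs are built codon-by-codon. Start codons, stop codons and incomplete
tails are pinned first (through shared overlap bases, where the frames of
both partners are honored); remaining codons are drawn with rejection of
TAA/TAG. Because rejection removes A/T-rich codons, draw probabilities are
recalibrated by iterative proportional fitting over the 62 non-stop codons
so the accepted stream matches the target per-base marginal — including
the A:T and G:C balance, not just the A+T level. A fraction (default 10%)
of free codons is emitted directly as TTA, emulating the strong UUA (Leu2)
preference of AT-biased mitogenomes and making TTA the modal codon
deterministically; its (A:⅓, T:⅔) contribution is folded out of the
i.i.d. share so composition targets still hold. Minority-strand genes are
drawn in coding sense with complemented targets, leaving the J-strand
composition unchanged. Control-region plants carry C/G guard bases on both
flanks so every planted element is maximal and recovered at its exact
coordinates; the CR filler composition is conditioned on the pinned bases
so the region still meets its A+T target. Everything is deterministic
under the seed, and a ground-truth sidecar records all realized
coordinates, codons and planted elements.

Expected accuracy of the A+T target is binomial: σ ≈ 100·√(p(1−p)/L),
about 0.32 percentage points at 80% and 15.3 kb; the recovery test demands
3σ agreement for ≥ 95% of seeds at targets 70/80/90%.

The study-like fixture set fixes the five genomes' exact lengths
(15,340/15,295/15,304/15,295/15,289 bp), whole-genome compositions
(A+T 80.0–80.8%, mean 80.34%), PCG totals (11,196/11,205/11,193/11,187/
11,199 bp), tRNA totals (1,458–1,470 bp), rRNA and control-region sizes
(262–285 bp) and poly-T lengths (14–26 bp) to the published per-species
values; quantities not printed for every species (middle CR lengths,
per-tRNA sizes, some rRNA lengths, specific (AT)n sets) are realistic
interpolations marked `synthetic` in `study.py`. One arithmetic constraint
is worth noting: the published PCG totals of the four non-Badamia species
are all ≡ 0 (mod 3) while four of their genes carry incomplete stops,
which forces two of those four to use the two-base tail TA- rather than
T-; the fixtures give cox1/cox2 the T- and nad4/nad5 the TA-.

## What the fixtures do and do not show

The generator reproduces the *structural* and *first-order compositional*
facts (lengths, totals, junction plan, planted CR elements, composition
levels and skews in expectation, modal TTA usage). It does not emulate
position-specific codon bias (so the "third codon position is most
AT-rich" pattern of real PCGs is absent), realistic tRNA/rRNA secondary
structure, between-gene compositional heterogeneity, or cross-taxon
homology (fixture gene sequences are independent draws, so real alignment
is meaningless on them — matrix tests use trailing-gap padding, explicitly
flagged unaligned). Passing tests therefore demonstrate correctness of the
arithmetic and scanners on genomes with known truth, not biological
realism of the sequences themselves.

## Numerical and degenerate-input choices

Skews raise on zero denominators rather than returning 0; empty or all-N
regions raise a dedicated composition error; a missing region class drops
its report row with a warning instead of failing the run. The comparative
report sorts genomes by id, computes summaries at full precision and
rounds only on output, contains no timestamps, and is byte-identical under
input permutation and re-runs. Problem sizes in the test suite and the
acceptance script (100 random layouts, 3 × 100 recovery seeds, 100 random
oracle strings of ≤ 500 bp) were chosen to give the property checks real
statistical teeth at interactive runtimes.

## Known limitations

No mismatch-tolerant repeat detection; no secondary-structure work; no
alignment, trimming, model selection or tree inference (external tools by
design); multi-record GenBank files are consumed record-by-record only;
the accession-replication checks require a one-time download of the
deposited records and otherwise stay dormant.
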