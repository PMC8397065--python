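"""Control-region scanners against brute-force and regex oracles."""

import random
import re

import pytest

from conftest import make_toy_genome
from mitochar.control_region import (
    analyze_control_region,
    find_dinucleotide_repeats,
    find_microsatellites_after_motif,
    find_origin_motif,
    find_tandem_repeats,
    locate_at_rich,
)
from mitochar.errors import AbsentControlRegionError


class TestOriginMotif:
    def test_direct_scan_example(self):
        assert find_origin_motif("GGATAGATTTTCC") == (2, 4)

    def test_absence_is_none(self):
        assert find_origin_motif("GGGGCCCC") is None

    def test_longest_poly_t_wins_ties_go_first(self):
        s = "ATAGATTcccATAGATTTTTcccATAGATT".upper()
        pos, n = find_origin_motif(s)
        assert (pos, n) == (10, 5)
        s2 = "ATAGATTTcccATAGATTT".upper()
        assert find_origin_motif(s2) == (0, 3)

    def test_motif_at_end_has_zero_poly_t(self):
        assert find_origin_motif("CCATAGA") == (2, 0)


class TestDinucleotideRepeats:
    def test_simple_run(self):
        assert find_dinucleotide_repeats("ATATATAT", min_copies=4) == [("AT", 4, 0)]

    def test_phase_shifted_run_reported_under_at(self):
        assert find_dinucleotide_repeats("GGTATATATAGG", min_copies=4) == [("AT", 4, 2)]

    def test_below_threshold_ignored(self):
        assert find_dinucleotide_repeats("ATATAT", min_copies=4) == []

    def test_min_copies_validated(self):
        with pytest.raises(ValueError):
            find_dinucleotide_repeats("ATAT", min_copies=1)

    def test_matches_regex_oracle_on_random_strings(self):
        rng = random.Random(13)
        pattern = re.compile(r"(?:AT){4,}|(?:TA){4,}")
        for _ in range(100):
            s = "".join(rng.choices("ATGC", weights=[4, 4, 1, 1], k=rng.randint(10, 500)))
            expected = [(m.start(), len(m.group()) // 2) for m in pattern.finditer(s)]
            got = [(pos, n) for _, n, pos in find_dinucleotide_repeats(s, min_copies=4)]
            assert got == expected


def _brute_force_tandems(s, max_unit, min_copies):
    """Quadratic oracle: every (start, unit) pair, maximal perfect runs,
    primitive units, leftmost starts, containment-filtered like the scanner."""
    n = len(s)
    runs = set()
    for u in range(1, max_unit + 1):
        for i in range(n - u):
            unit = s[i: i + u]
            # primitive?
            if any(u % p == 0 and unit == unit[:p] * (u // p) for p in range(1, u)):
                continue
            # maximal to the left: previous base must break the period
            if i >= 1 and s[i - 1] == s[i - 1 + u]:
                continue
            j = i
            while j < n - u and s[j] == s[j + u]:
                j += 1
            if j == i:
                continue
            span = j - i + u
            copies = span // u
            if copies >= min_copies:
                runs.add((unit, copies, i, span))
    # drop runs contained in an equal-or-longer run of smaller unit
    out = []
    for r in runs:
        if any(
            k[2] <= r[2] and k[2] + k[3] >= r[2] + r[3] and len(k[0]) < len(r[0])
            for k in runs
            if k != r
        ):
            continue
        out.append(r)
    return sorted(out, key=lambda r: (r[2], len(r[0])))


class TestTandemRepeats:
    def test_trinucleotide_run(self):
        reps = find_tandem_repeats("ACGACGACG", max_unit=6, min_copies=3)
        assert [(r.unit, r.copies, r.start) for r in reps] == [("ACG", 3, 0)]

    def test_primitive_unit_only(self):
        reps = find_tandem_repeats("AAAA", max_unit=2, min_copies=2)
        assert [(r.unit, r.copies) for r in reps] == [("A", 4)]

    def test_matches_quadratic_oracle_on_random_strings(self):
        rng = random.Random(31)
        for _ in range(100):
            s = "".join(rng.choices("ATGC", weights=[4, 4, 1, 1], k=rng.randint(10, 500)))
            got = [(r.unit, r.copies, r.start, r.span) for r in find_tandem_repeats(s, max_unit=4, min_copies=3)]
            assert got == _brute_force_tandems(s, max_unit=4, min_copies=3)

    def test_direction_invariance_for_perfect_repeats(self):
        # reversal rotates the repeat unit, so compare rotation-canonical units
        def canon(u):
            return min(u[i:] + u[:i] for i in range(len(u)))

        s = "GGACGACGACGGG"
        fwd = find_tandem_repeats(s, max_unit=4, min_copies=3)
        rev = find_tandem_repeats(s[::-1], max_unit=4, min_copies=3)
        assert sorted((canon(r.unit[::-1]), r.copies, r.span) for r in rev) == sorted(
            (canon(r.unit), r.copies, r.span) for r in fwd
        )


class TestMicrosatellitesAfterMotif:
    def test_anchored_ta_run(self):
        reps = find_microsatellites_after_motif("ATTTATATATATA")
        assert [(r.unit, r.copies, r.start) for r in reps] == [("TA", 4, 5)]

    def test_no_anchor_empty(self):
        assert find_microsatellites_after_motif("GGGGCCCCGGGG") == []

    def test_repeat_outside_window_ignored(self):
        s = "ATTTA" + "GCAGTCAGGTCA" + "ACGACGACG"  # run starts 12 bp downstream
        assert find_microsatellites_after_motif(s, window=10) == []


class TestLocateAtRich:
    def test_annotated_feature_verbatim(self):
        g = make_toy_genome(
            "A" * 40,
            [("rrnS", "rRNA", 0, 10, "N"), ("AT-rich", "control-region", 12, 30, "J"), ("trnM", "tRNA", 32, 40, "J")],
        )
        assert locate_at_rich(g) == (12, 30)

    def test_fallback_rrns_trnm_gap_with_wrap(self):
        g = make_toy_genome(
            "A" * 40,
            [("trnM", "tRNA", 10, 18, "J"), ("rrnS", "rRNA", 30, 38, "N")],
        )
        assert locate_at_rich(g) == (38, 50)  # wraps: 12 bp across the origin

    def test_absent_cr_errors(self):
        g = make_toy_genome("A" * 20, [("trnM", "tRNA", 0, 10, "J"), ("rrnS", "rRNA", 10, 20, "N")])
        with pytest.raises(AbsentControlRegionError):
            locate_at_rich(g)


def test_planted_elements_recovered_exactly(fixture_set):
    """Detection completeness on generator output: motif, poly-T, every (AT)n
    and the anchored microsatellite, all at exact planted coordinates."""
    for genome, truth in fixture_set:
        el = analyze_control_region(genome)
        planted = truth.cr_elements
        assert el.cr_length == truth.cr_interval[1] - truth.cr_interval[0]
        assert el.origin_motif == (
            planted["origin_motif"]["position"],
            planted["origin_motif"]["poly_t_length"],
        )
        detected_at = {(pos, n) for _, n, pos in el.dinucleotide_repeats}
        for rep in planted["at_repeats"]:
            assert (rep["position"], rep["copies"]) in detected_at
        ms = planted["microsatellite"]
        assert any(
            (r.start, r.unit, r.copies) == (ms["position"], ms["unit"], ms["copies"])
            for r in el.atta_microsatellites
        )
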