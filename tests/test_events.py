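"""Splice-event classification between isoform pairs."""

import numpy as np
import pytest

from isoswitch.events import affected_junction_regions, classify_pair
from isoswitch.genome import ValidationError

from _oracles import oracle_classify
from conftest import make_tx


def classes(events):
    return [e.event_class for e in events]


class TestElementaryClasses:
    def test_identical_transcripts_give_no_events(self):
        a = make_tx([(0, 100), (200, 300), (400, 500)], "a")
        b = make_tx([(0, 100), (200, 300), (400, 500)], "b")
        events = classify_pair(a, b)
        assert list(events) == [] and not events.no_common_frame

    def test_exon_skip_coordinates_and_junctions(self):
        a = make_tx([(0, 100), (200, 300), (400, 500)], "a")
        b = make_tx([(0, 100), (400, 500)], "b")
        (event,) = classify_pair(a, b)
        assert event.event_class == "ES"
        assert (event.variable_start, event.variable_end) == (200, 300)
        assert {j.interval for j in event.junctions_a} == {(100, 200), (300, 400)}
        assert {j.interval for j in event.junctions_b} == {(100, 400)}

    def test_intron_retention(self):
        a = make_tx([(0, 100), (200, 300)], "a")
        b = make_tx([(0, 300)], "b")
        (event,) = classify_pair(a, b)
        assert event.event_class == "IR"
        assert (event.variable_start, event.variable_end) == (100, 200)

    def test_alternative_donor(self):
        a = make_tx([(0, 100), (200, 300)], "a")
        b = make_tx([(0, 120), (200, 300)], "b")
        (event,) = classify_pair(a, b)
        assert event.event_class == "A5"
        assert (event.variable_start, event.variable_end) == (100, 120)

    def test_alternative_acceptor(self):
        a = make_tx([(0, 100), (200, 300)], "a")
        b = make_tx([(0, 100), (180, 300)], "b")
        (event,) = classify_pair(a, b)
        assert event.event_class == "A3"

    def test_mutually_exclusive_exons(self):
        a = make_tx([(0, 100), (200, 250), (400, 500)], "a")
        b = make_tx([(0, 100), (300, 350), (400, 500)], "b")
        (event,) = classify_pair(a, b)
        assert event.event_class == "ME"
        assert (event.variable_start, event.variable_end) == (200, 350)

    def test_double_skip_is_complex(self):
        a = make_tx([(0, 10), (20, 30), (40, 50), (60, 70)], "a")
        b = make_tx([(0, 10), (60, 70)], "b")
        (event,) = classify_pair(a, b)
        assert event.event_class == "complex"

    def test_terminal_differences_excluded(self):
        # first-exon length difference beyond the outermost shared site is an
        # alternative start, not a splicing event
        a = make_tx([(0, 100), (200, 300)], "a")
        b = make_tx([(50, 100), (200, 300)], "b")
        assert list(classify_pair(a, b)) == []

    def test_no_common_frame_flagged(self):
        # no shared splice site and no shared transcript terminus
        a = make_tx([(0, 100), (200, 300)], "a")
        b = make_tx([(10, 110), (220, 310)], "b")
        events = classify_pair(a, b)
        assert list(events) == [] and events.no_common_frame

    def test_incompatible_transcripts_raise(self):
        a = make_tx([(0, 100), (200, 300)], "a", strand="+")
        b = make_tx([(0, 100), (200, 300)], "b", strand="-")
        with pytest.raises(ValidationError):
            classify_pair(a, b)


class TestSymmetries:
    PAIRS = [
        ([(0, 100), (200, 300), (400, 500)], [(0, 100), (400, 500)]),
        ([(0, 100), (200, 300)], [(0, 300)]),
        ([(0, 100), (200, 300)], [(0, 120), (200, 300)]),
        ([(0, 100), (200, 250), (400, 500)], [(0, 100), (300, 350), (400, 500)]),
    ]

    @pytest.mark.parametrize("exons_a,exons_b", PAIRS)
    def test_argument_order_does_not_change_events(self, exons_a, exons_b):
        a, b = make_tx(exons_a, "a"), make_tx(exons_b, "b")
        fwd = classify_pair(a, b)
        rev = classify_pair(b, a)
        assert classes(fwd) == classes(rev)
        assert [(e.variable_start, e.variable_end) for e in fwd] == \
               [(e.variable_start, e.variable_end) for e in rev]

    @pytest.mark.parametrize("exons_a,exons_b", PAIRS)
    def test_strand_relabel_swaps_donor_acceptor_classes(self, exons_a, exons_b):
        # same exon chains declared on the minus strand: what was a donor-side
        # boundary becomes acceptor-side, so A5 and A3 swap while ES/IR/ME
        # are unaffected
        fwd = classes(classify_pair(make_tx(exons_a, "a"), make_tx(exons_b, "b")))
        swap = {"A5": "A3", "A3": "A5"}
        flipped = classes(classify_pair(
            make_tx(exons_a, "a", strand="-"), make_tx(exons_b, "b", strand="-"),
        ))
        assert flipped == [swap.get(c, c) for c in fwd]

    @pytest.mark.parametrize("exons_a,exons_b", PAIRS)
    def test_mirror_with_strand_flip_preserves_classes(self, exons_a, exons_b):
        # reflecting coordinates and flipping the strand describes the same
        # molecule, so every event class must be preserved
        m = 1000

        def mirror(exons):
            return sorted((m - e, m - s) for s, e in exons)

        fwd = classes(classify_pair(make_tx(exons_a, "a"), make_tx(exons_b, "b")))
        mirrored = classes(classify_pair(
            make_tx(mirror(exons_a), "a", strand="-"),
            make_tx(mirror(exons_b), "b", strand="-"),
        ))
        assert mirrored == fwd


class TestOracleAgreement:
    def test_random_chain_pairs_match_coverage_oracle(self, rng):
        grid = list(range(12))
        n_checked = 0
        for _ in range(800):
            k1, k2 = rng.integers(1, 5, size=2)
            pos_a = sorted(rng.choice(grid, size=2 * k1, replace=False))
            pos_b = sorted(rng.choice(grid, size=2 * k2, replace=False))
            exons_a = [(pos_a[i], pos_a[i + 1]) for i in range(0, 2 * k1, 2)]
            exons_b = [(pos_b[i], pos_b[i + 1]) for i in range(0, 2 * k2, 2)]
            expected = oracle_classify(exons_a, exons_b, "+")
            got = classify_pair(make_tx(exons_a, "a"), make_tx(exons_b, "b"))
            if expected is None:
                assert got.no_common_frame
                continue
            assert [(e.event_class, e.variable_start, e.variable_end)
                    for e in got] == expected
            n_checked += 1
        assert n_checked > 100


class TestAffectedJunctionRegions:
    def test_retained_intron_yields_its_own_junction(self):
        a = make_tx([(0, 100), (200, 300)], "a")
        b = make_tx([(0, 300)], "b")
        (event,) = classify_pair(a, b)
        (junction,) = affected_junction_regions(event)
        assert junction.interval == (100, 200)

    def test_exon_skip_yields_flanking_introns(self):
        a = make_tx([(0, 100), (200, 300), (400, 500)], "a")
        b = make_tx([(0, 100), (400, 500)], "b")
        (event,) = classify_pair(a, b)
        intervals = {j.interval for j in affected_junction_regions(event)}
        assert intervals == {(100, 200), (300, 400)}

    def test_skipping_plus_double_retention_on_one_gene(self):
        # a gene can simultaneously show a cassette-exon skip in one variant
        # and retention of the two introns flanking that exon in another:
        # one ES event plus two IR events across the gene's isoform pairs
        ref = make_tx([(0, 100), (300, 400), (600, 700), (900, 1000)], "ref")
        skip = make_tx([(0, 100), (600, 700), (900, 1000)], "skip")
        retain = make_tx([(0, 700), (900, 1000)], "retain")
        assert classes(classify_pair(ref, skip)) == ["ES"]
        retention_events = classify_pair(ref, retain)
        assert classes(retention_events) == ["complex"]
        junctions = affected_junction_regions(retention_events[0])
        assert {j.interval for j in junctions} == {(100, 300), (400, 600)}

    def test_two_separate_retained_introns_give_two_ir_events(self):
        ref = make_tx([(0, 100), (200, 300), (400, 500), (600, 700),
                       (800, 900), (1000, 1100)], "ref")
        var = make_tx([(0, 100), (200, 500), (600, 900), (1000, 1100)], "var")
        events = classify_pair(ref, var)
        assert classes(events) == ["IR", "IR"]
        assert [(e.variable_start, e.variable_end) for e in events] == \
               [(300, 400), (700, 800)]
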