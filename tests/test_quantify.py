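"""Cut-window efficiency, frameshift, HDR and heterogeneity quantification."""

from __future__ import annotations

import math

import numpy as np
import pytest

from editscan.align import EditEvent, needleman_wunsch, reverse_complement
from editscan.normalize_filter import EventTable
from editscan.quantify import (
    CutWindow,
    classify_frameshift,
    compute_efficiency,
    compute_heterogeneity,
    hdr_expected_events,
    locate_cut_window,
    quantify_hdr,
)

from helpers import random_seq


def _del(start, width, read_id):
    return EditEvent("deletion", start, start + width, "N" * width, "", read_id)


def _ins(start, seq, read_id):
    return EditEvent("insertion", start, start, "", seq, read_id)


def _amplicon_with_guide(rng, length=100, guide_at=40):
    while True:
        amp = random_seq(rng, length)
        guide = amp[guide_at : guide_at + 20]
        if amp.count(guide) + amp.count(reverse_complement(guide)) == 1:
            return amp, guide


class TestLocateCutWindow:
    def test_forward_guide_blunt_cut_minus_three(self, rng):
        amp, guide = _amplicon_with_guide(rng)
        w = locate_cut_window(amp, guide)
        # guide at 40, length 20 -> cut at 57, window [52, 62)
        assert (w.start, w.end) == (52, 62)
        assert w.source == "guide_derived"

    def test_reverse_strand_guide_mirrored(self, rng):
        amp, guide = _amplicon_with_guide(rng)
        w_fwd = locate_cut_window(amp, guide)
        w_rev = locate_cut_window(reverse_complement(amp), guide)
        L = len(amp)
        assert (w_rev.start, w_rev.end) == (L - w_fwd.end, L - w_fwd.start)

    def test_user_override_returned_unchanged(self, rng):
        amp, _ = _amplicon_with_guide(rng)
        w = locate_cut_window(amp, "", override=(30, 80))
        assert (w.start, w.end, w.source) == (30, 80, "user_override")

    def test_absent_guide_errors(self, rng):
        amp, _ = _amplicon_with_guide(rng)
        with pytest.raises(ValueError, match="0 times"):
            locate_cut_window(amp, "T" * 20)

    def test_window_clamped_to_amplicon(self, rng):
        rng2 = np.random.default_rng(5)
        while True:
            amp = random_seq(rng2, 40)
            guide = amp[0:20]
            if amp.count(guide) + amp.count(reverse_complement(guide)) == 1:
                break
        w = locate_cut_window(amp, guide, flank=30)
        assert w.start == 0 and w.end == 40


class TestComputeEfficiency:
    def test_fraction_of_reads_with_window_indels(self):
        window = CutWindow(52, 62)
        events = [_del(55, 3, f"e{i}") for i in range(140)]
        table = EventTable("E", events=events, read_count_total=1000)
        stats = compute_efficiency(table, window)
        assert stats.reads_edited == 140
        assert stats.efficiency_pct == 14.0

    def test_indel_outside_window_not_counted(self):
        window = CutWindow(52, 62)
        table = EventTable("E", events=[_del(10, 5, "r0")], read_count_total=10)
        assert compute_efficiency(table, window).reads_edited == 0

    def test_deletion_straddling_window_edge_counts(self):
        window = CutWindow(52, 62)
        table = EventTable("E", events=[_del(45, 8, "r0")], read_count_total=10)
        assert compute_efficiency(table, window).reads_edited == 1

    def test_insertion_counts_only_if_anchor_in_window(self):
        window = CutWindow(52, 62)
        inside = EventTable("E", events=[_ins(52, "GG", "r0")], read_count_total=10)
        outside = EventTable("E", events=[_ins(62, "GG", "r0")], read_count_total=10)
        assert compute_efficiency(inside, window).reads_edited == 1
        assert compute_efficiency(outside, window).reads_edited == 0

    def test_mismatches_never_count(self):
        window = CutWindow(52, 62)
        table = EventTable(
            "E",
            events=[EditEvent("mismatch", 55, 56, "A", "C", "r0")],
            read_count_total=10,
        )
        assert compute_efficiency(table, window).reads_edited == 0

    def test_zero_events_zero_percent(self):
        stats = compute_efficiency(
            EventTable("E", read_count_total=100), CutWindow(52, 62)
        )
        assert stats.efficiency_pct == 0.0

    def test_no_reads_is_an_error(self):
        with pytest.raises(ValueError, match="no retained reads"):
            compute_efficiency(EventTable("E"), CutWindow(52, 62))

    def test_frameshift_bounded_by_efficiency_and_order_invariant(self, rng):
        window = CutWindow(52, 62)
        events = []
        for i in range(300):
            events.append(_del(int(rng.integers(40, 70)), int(rng.integers(1, 7)), f"r{i}"))
        table = EventTable("E", events=events, read_count_total=500)
        stats = compute_efficiency(table, window)
        assert stats.frameshift_pct <= stats.efficiency_pct
        shuffled = list(events)
        rng.shuffle(shuffled)
        stats2 = compute_efficiency(
            EventTable("E", events=shuffled, read_count_total=500), window
        )
        assert stats2.efficiency_pct == stats.efficiency_pct
        # duplicating the whole read set leaves percentages unchanged
        doubled = events + [
            EditEvent(e.type, e.start, e.end, e.originally, e.replacement, "d" + e.read_id)
            for e in events
        ]
        stats3 = compute_efficiency(
            EventTable("E", events=doubled, read_count_total=1000), window
        )
        assert stats3.efficiency_pct == stats.efficiency_pct


class TestClassifyFrameshift:
    @pytest.mark.parametrize(
        "events,expected",
        [
            ([_del(50, 11, "r")], True),  # 11 mod 3 = 2
            ([_del(50, 3, "r")], False),  # in-frame
            ([_ins(50, "GG", "r"), _del(60, 1, "r")], True),  # net +1
            ([_ins(50, "GGG", "r")], False),
            ([EditEvent("mismatch", 50, 51, "A", "C", "r")], False),
        ],
    )
    def test_net_indel_length_mod_three(self, events, expected):
        assert classify_frameshift(events) is expected


class TestHdr:
    def test_donor_insertion_yields_expected_insertion(self, rng):
        amp, _ = _amplicon_with_guide(rng)
        donor = amp[:57] + "GGATCC" + amp[57:]
        expected = hdr_expected_events(donor, amp)
        assert len(expected) == 1
        assert expected[0].type == "insertion"
        assert expected[0].replacement == "GGATCC"

    def test_base_editor_donor_yields_mismatch(self, rng):
        amp, _ = _amplicon_with_guide(rng)
        pos = 57
        new = "T" if amp[pos] != "T" else "A"
        donor = amp[:pos] + new + amp[pos + 1 :]
        expected = hdr_expected_events(donor, amp)
        assert expected == [EditEvent("mismatch", pos, pos + 1, amp[pos], new, "__donor__")]

    def test_two_base_substitution_block_gives_adjacent_mismatches(self, rng):
        amp, _ = _amplicon_with_guide(rng)
        sub = "".join("ACGT"[("ACGT".index(b) + 2) % 4] for b in amp[57:59])
        donor = amp[:57] + sub + amp[59:]
        expected = hdr_expected_events(donor, amp)
        assert [e.type for e in expected] == ["mismatch", "mismatch"]
        assert [e.start for e in expected] == [57, 58]

    def test_identical_donor_rejected(self, rng):
        amp, _ = _amplicon_with_guide(rng)
        with pytest.raises(ValueError, match="identical"):
            hdr_expected_events(amp, amp)

    def test_hdr_nhej_fractions(self):
        window = CutWindow(52, 62)
        expected = [_ins(57, "GGATCC", "__donor__")]
        events = []
        for i in range(200):  # perfect integrations
            events.append(_ins(57, "GGATCC", f"h{i}"))
        for i in range(300):  # cut-site indels without the donor event
            events.append(_del(55, 4, f"n{i}"))
        table = EventTable("E", events=events, read_count_total=1000)
        stats = quantify_hdr(table, expected, window)
        assert (stats.hdr_pct, stats.nhej_pct) == (20.0, 30.0)
        assert stats.reads_hdr + stats.reads_nhej <= stats.reads_total

    def test_hdr_read_with_extra_indel_still_hdr(self):
        window = CutWindow(52, 62)
        expected = [_ins(57, "GGATCC", "__donor__")]
        events = [_ins(57, "GGATCC", "h0"), _del(70, 1, "h0")]
        table = EventTable("E", events=events, read_count_total=10)
        stats = quantify_hdr(table, expected, window)
        assert stats.reads_hdr == 1 and stats.reads_nhej == 0

    def test_no_expected_events_found_zero_hdr(self):
        window = CutWindow(52, 62)
        expected = [_ins(57, "GGATCC", "__donor__")]
        table = EventTable("E", events=[_del(55, 2, "r0")], read_count_total=10)
        stats = quantify_hdr(table, expected, window)
        assert stats.hdr_pct == 0.0 and stats.reads_nhej == 1


class TestHeterogeneity:
    def test_uniform_population_zero_entropy(self):
        summary = compute_heterogeneity(EventTable("E", read_count_total=100))
        assert summary.n_signatures == 1
        assert summary.entropy_bits == 0.0

    def test_two_equal_signatures_one_bit(self):
        events = [_del(50, 3, f"r{i}") for i in range(50)]
        summary = compute_heterogeneity(
            EventTable("E", events=events, read_count_total=100)
        )
        assert summary.n_signatures == 2
        assert summary.entropy_bits == pytest.approx(1.0)

    def test_entropy_matches_direct_computation_on_truth(self, rng):
        counts = [60, 25, 10, 5]
        events = []
        rid = 0
        for k, c in enumerate(counts[1:], start=1):
            for _ in range(c):
                events.append(_del(10 * k, k, f"r{rid}"))
                rid += 1
        summary = compute_heterogeneity(
            EventTable("E", events=events, read_count_total=sum(counts))
        )
        expected = -sum(
            (c / 100) * math.log2(c / 100) for c in counts
        )
        assert summary.entropy_bits == pytest.approx(expected)
        assert summary.n_signatures == 4
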