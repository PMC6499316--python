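"""Primer-dimer removal, artifact flagging, control normalization."""

from __future__ import annotations

import numpy as np
import pytest

from editscan.align import AlignedRead, EditEvent
from editscan.normalize_filter import (
    ArtifactModel,
    EventTable,
    detect_primer_dimer,
    flag_artifact_reads,
    merge_event_tables,
    normalize_with_control,
)
from editscan.pipeline import PipelineParams, align_experiment, build_event_table
from editscan.config_io import ExperimentRecord, SequencedRead
from editscan.simulate import simulate_contaminants

from helpers import random_seq


def _del(start, width, read_id, ref="A"):
    return EditEvent("deletion", start, start + width, ref * width, "", read_id)


def _ins(start, seq, read_id):
    return EditEvent("insertion", start, start, "", seq, read_id)


class TestPrimerDimer:
    # amplicon 150, primers 20+20, buffer 30 -> deletion threshold 80
    def test_oversized_deletion_flagged(self):
        assert detect_primer_dimer([_del(25, 90, "r")], 150, 20, 20, 30)

    def test_threshold_is_strict(self):
        assert not detect_primer_dimer([_del(25, 80, "r")], 150, 20, 20, 30)
        assert detect_primer_dimer([_del(25, 81, "r")], 150, 20, 20, 30)

    def test_read_without_deletions_passes(self):
        assert not detect_primer_dimer(
            [_ins(30, "GG", "r"), EditEvent("mismatch", 5, 6, "A", "C", "r")],
            150, 20, 20, 30,
        )


def _aligned(read_id, events, length=200):
    return AlignedRead(
        read_id=read_id, experiment_id="E", score_fwd=0, events=events,
        span=(0, length),
    )


class TestArtifactFlagging:
    def test_contaminated_library_separated_from_clean_reads(self, rng):
        """Reads at a 30% per-base mismatch rate are flagged; clean on-target
        reads are not."""
        amp = random_seq(rng, 200)
        reads = []
        for i in range(1000):
            reads.append(_aligned(f"clean{i}", []))
        for i, seq in enumerate(
            simulate_contaminants(amp, 0.30, 50, seed=rng)
        ):
            events = [
                EditEvent("mismatch", p, p + 1, amp[p], seq[p], f"cont{i}")
                for p in range(200)
                if seq[p] != amp[p]
            ]
            reads.append(_aligned(f"cont{i}", events))
        flagged = flag_artifact_reads(reads)
        assert flagged == {f"cont{i}" for i in range(50)}

    def test_all_identical_reads_unflagged(self):
        assert flag_artifact_reads([_aligned(f"r{i}", []) for i in range(100)]) == set()

    def test_flagging_enriches_contaminants_at_every_rate(self, rng):
        """At per-base mismatch rates 10%-50% the flagged fraction among true
        contaminants is always >= the flagged fraction among clean reads."""
        amp = random_seq(rng, 200)
        for rate in (0.10, 0.20, 0.30, 0.40, 0.50):
            reads = [_aligned(f"clean{i}", []) for i in range(400)]
            for i, seq in enumerate(simulate_contaminants(amp, rate, 100, seed=rng)):
                events = [
                    EditEvent("mismatch", p, p + 1, amp[p], seq[p], f"cont{i}")
                    for p in range(200)
                    if seq[p] != amp[p]
                ]
                reads.append(_aligned(f"cont{i}", events))
            flagged = flag_artifact_reads(reads)
            frac_cont = sum(1 for r in flagged if r.startswith("cont")) / 100
            frac_clean = sum(1 for r in flagged if r.startswith("clean")) / 400
            assert frac_cont >= frac_clean
            assert frac_cont > 0.9  # detection, not just enrichment

    def test_excessive_indel_count_flagged(self):
        events = [_del(10 * k, 2, "messy") for k in range(1, 6)]
        reads = [_aligned("messy", events)] + [
            _aligned(f"r{i}", []) for i in range(20)
        ]
        assert flag_artifact_reads(reads, ArtifactModel(max_indel_events=4)) == {
            "messy"
        }


def _table(events, total, exp="T"):
    return EventTable(experiment_id=exp, events=events, read_count_total=total)


class TestNormalization:
    def test_shared_background_deletion_removed(self):
        """An 11-bp deletion present at 9% in both treatment and control is
        background, not editing: normalization removes it everywhere."""
        treat = _table(
            [_del(50, 11, f"t{i}") for i in range(90)], 1000
        )
        ctrl = _table([_del(50, 11, f"c{i}") for i in range(90)], 1000, exp="C")
        out = normalize_with_control(treat, ctrl)
        assert out.events == []
        assert out.read_count_total == 1000

    def test_threshold_is_strictly_above(self):
        treat = _table([_del(50, 11, f"t{i}") for i in range(90)], 1000)
        at_thr = _table([_del(50, 11, f"c{i}") for i in range(9)], 900, exp="C")
        # 9/900 = 1.0% is not *above* the 1% threshold -> retained
        assert len(normalize_with_control(treat, at_thr).events) == 90
        above = _table([_del(50, 11, f"c{i}") for i in range(10)], 900, exp="C")
        assert normalize_with_control(treat, above).events == []

    def test_empty_control_events_leave_treatment_unchanged(self):
        treat = _table([_del(5, 2, "t0")], 100)
        out = normalize_with_control(treat, _table([], 100, exp="C"))
        assert out.events == treat.events

    def test_control_without_reads_warns_and_returns_treatment(self):
        treat = _table([_del(5, 2, "t0")], 100)
        with pytest.warns(UserWarning, match="no reads"):
            out = normalize_with_control(treat, _table([], 0, exp="C"))
        assert out.events == treat.events

    def test_positional_slack_matches_shifted_background(self):
        treat = _table([_del(52, 11, f"t{i}") for i in range(90)], 1000)
        ctrl = _table([_del(50, 11, f"c{i}") for i in range(90)], 1000, exp="C")
        # exact matching keeps the (differently placed) treatment event
        assert len(normalize_with_control(treat, ctrl).events) == 90
        # 2 bp of slack treats it as the same background deletion
        assert normalize_with_control(treat, ctrl, slack=2).events == []

    def test_co_occurring_novel_event_survives(self):
        """A read carrying a control-shared deletion plus a novel insertion
        keeps the insertion: reads are never discarded, only shared events."""
        shared = [_del(50, 11, f"t{i}") for i in range(200)]
        novel = _ins(52, "GG", "t0")
        treat = _table(shared + [novel], 1000)
        ctrl = _table([_del(50, 11, f"c{i}") for i in range(200)], 1000, exp="C")
        out = normalize_with_control(treat, ctrl)
        assert out.events == [novel]
        assert out.read_count_total == 1000

    def test_idempotent_and_monotone_on_random_tables(self, rng):
        for trial in range(25):
            n_t, n_c = 200, 200
            def rand_events(prefix, n_reads):
                events = []
                for i in range(n_reads):
                    for _ in range(int(rng.integers(0, 3))):
                        start = int(rng.integers(0, 40))
                        if rng.random() < 0.5:
                            events.append(_del(start, int(rng.integers(1, 4)), f"{prefix}{i}"))
                        else:
                            events.append(_ins(start, "ACGT"[: int(rng.integers(1, 4))], f"{prefix}{i}"))
                return events
            treat = _table(rand_events("t", n_t), n_t)
            ctrl = _table(rand_events("c", n_c), n_c, exp="C")
            once = normalize_with_control(treat, ctrl)
            twice = normalize_with_control(once, ctrl)
            assert twice.events == once.events  # idempotence
            assert once.read_count_total == treat.read_count_total
            # monotonicity: normalized reads-with-events <= raw
            assert len({e.read_id for e in once.events}) <= len(
                {e.read_id for e in treat.events}
            )
            kept = {e.identity for e in once.events}
            assert kept <= {e.identity for e in treat.events}


class TestMergeTables:
    def test_union_of_controls_pools_reads_and_events(self):
        a = _table([_del(5, 2, "x")], 100, exp="C1")
        b = _table([_del(5, 2, "x")], 300, exp="C2")
        merged = merge_event_tables([a, b], "ctrl")
        assert merged.read_count_total == 400
        assert len(merged.events) == 2
        # the same local read id from different controls stays distinct
        assert len({e.read_id for e in merged.events}) == 2
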