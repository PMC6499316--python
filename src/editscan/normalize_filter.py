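"""Artifact filtering and control-based event-level normalization.

Two read-level filters remove experimental artifacts before quantification:
primer dimers (reads whose alignment implies a deletion spanning nearly the
whole insert) and off-target/artifact reads (reads with far more mismatches
than the bulk, or with an implausible number of indel events).

Normalization then subtracts the background seen in the matched control:
any specific event (same type, coordinates and sequence after
left-normalization) observed in the control above a noise threshold
(default 1% of control reads) is removed from the treatment.  Reads are
never removed by normalization -- only the shared events stop being
counted, so genuine edits co-occurring on the same read survive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import binom

from .align import AlignedRead, EditEvent

__all__ = [
    "EventTable",
    "ArtifactModel",
    "detect_primer_dimer",
    "flag_artifact_reads",
    "normalize_with_control",
    "merge_event_tables",
]


@dataclass
class EventTable:
    """All events of one experiment plus the read universe they came from.

    ``read_count_total`` counts the retained (assigned, quality-passing,
    unflagged) reads and is the denominator of every frequency; reads with no
    events are part of it.
    """

    experiment_id: str
    events: list[EditEvent] = field(default_factory=list)
    read_count_total: int = 0
    reads_flagged: dict = field(default_factory=dict)
    read_scores: dict = field(default_factory=dict)

    def events_by_read(self) -> dict[str, list[EditEvent]]:
        out: dict[str, list[EditEvent]] = {}
        for ev in self.events:
            out.setdefault(ev.read_id, []).append(ev)
        return out

    def event_frequencies(self) -> dict[tuple, float]:
        """Frequency of each event identity: carrying reads / total reads."""
        if self.read_count_total == 0:
            return {}
        carriers: dict[tuple, set] = {}
        for ev in self.events:
            carriers.setdefault(ev.identity, set()).add(ev.read_id)
        return {
            k: len(v) / self.read_count_total for k, v in carriers.items()
        }


def detect_primer_dimer(
    events: list[EditEvent],
    amplicon_length: int,
    fwd_primer_length: int,
    rev_primer_length: int,
    buffer: int = 30,
) -> bool:
    """True iff any single deletion exceeds the primer-dimer threshold.

    A primer dimer contains the two primers but almost none of the insert, so
    its alignment shows a deletion wider than
    ``amplicon - fwd_primer - rev_primer - buffer`` (strict inequality).
    """
    threshold = amplicon_length - fwd_primer_length - rev_primer_length - buffer
    return any(
        ev.type == "deletion" and ev.width > threshold for ev in events
    )


@dataclass(frozen=True)
class ArtifactModel:
    """Parameters of the off-target/artifact read filter."""

    alpha: float = 1e-3
    max_indel_events: int = 4


def flag_artifact_reads(
    aligned: list[AlignedRead], model: ArtifactModel | None = None
) -> set[str]:
    """Read ids of likely off-target or artifact reads.

    A per-base mismatch noise rate is estimated by pooling mismatch events
    over all reads (with a +1/+2 pseudocount so an error-free experiment has
    a nonzero rate).  A read is flagged when the upper tail probability of
    its mismatch count under Binomial(covered length, noise rate) falls below
    ``alpha`` -- i.e. it carries far more mismatches than the bulk of the
    library explains -- or when it has more than ``max_indel_events`` indel
    events.
    """
    model = model or ArtifactModel()
    if not aligned:
        return set()
    mm_counts = np.array(
        [sum(1 for e in r.events if e.type == "mismatch") for r in aligned]
    )
    lengths = np.array([max(r.span[1] - r.span[0], 1) for r in aligned])
    indels = np.array(
        [sum(1 for e in r.events if e.type != "mismatch") for r in aligned]
    )
    rate = (mm_counts.sum() + 1) / (lengths.sum() + 2)
    tail = binom.sf(mm_counts - 1, lengths, rate)  # P(X >= observed)
    flagged = (tail < model.alpha) | (indels > model.max_indel_events)
    return {r.read_id for r, f in zip(aligned, flagged) if f}


def normalize_with_control(
    treatment: EventTable,
    control: EventTable,
    min_control_freq: float = 0.01,
    slack: int = 0,
) -> EventTable:
    """Remove treatment events present in the control above the noise level.

    An event is removed iff an identical event (type, left-normalized
    coordinates, replacement sequence) occurs in the control at a frequency
    strictly greater than ``min_control_freq``.  Left-normalization makes
    placement canonical, so exact identity is the default; ``slack`` > 0
    additionally matches control events of the same type, width and
    replacement whose start lies within ``slack`` bp.  ``read_count_total``
    is unchanged: normalization never discards reads, and other events on
    affected reads are retained.
    """
    if control.read_count_total == 0:
        warnings.warn(
            f"control for {treatment.experiment_id!r} has no reads; "
            f"treatment returned unnormalized",
            stacklevel=2,
        )
        return replace(treatment, events=list(treatment.events))
    ctrl_freq = control.event_frequencies()
    background = {
        ident for ident, f in ctrl_freq.items() if f > min_control_freq
    }

    if slack == 0:
        kept = [ev for ev in treatment.events if ev.identity not in background]
    else:

        def matches_background(ev: EditEvent) -> bool:
            if ev.identity in background:
                return True
            for btype, bstart, bend, brepl in background:
                if (
                    btype == ev.type
                    and brepl == ev.replacement
                    and (bend - bstart) == (ev.end - ev.start)
                    and abs(bstart - ev.start) <= slack
                ):
                    return True
            return False

        kept = [ev for ev in treatment.events if not matches_background(ev)]
    return replace(treatment, events=kept)


def merge_event_tables(tables: list[EventTable], experiment_id: str) -> EventTable:
    """Pool several control tables into one (union of reads and events)."""
    merged = EventTable(experiment_id=experiment_id)
    for i, t in enumerate(tables):
        prefix = f"c{i}:" if len(tables) > 1 else ""
        merged.events.extend(
            replace(ev, read_id=prefix + ev.read_id) for ev in t.events
        )
        merged.read_count_total += t.read_count_total
    return merged
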