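"""Editing-outcome quantification: efficiency, frameshift, HDR, heterogeneity.

A read counts as edited when it carries at least one insertion or deletion
overlapping a window around the expected double-strand break (default ±5 bp
of the blunt SpCas9 cut 3 nt 5' of the PAM).  Mismatches never count toward
indel efficiency.  Frameshift status sums the impact of all retained indels
on the read (net length mod 3).  HDR is quantified by first aligning the
donor template to the amplicon to obtain the expected events of a successful
integration, then counting the reads carrying all of them; this same path
quantifies base editors via donors that alter single target bases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .align import (
    EditEvent,
    ScoringScheme,
    extract_events,
    needleman_wunsch,
    reverse_complement,
)
from .normalize_filter import EventTable

__all__ = [
    "CutWindow",
    "EditingStats",
    "HeterogeneitySummary",
    "locate_cut_window",
    "compute_efficiency",
    "classify_frameshift",
    "hdr_expected_events",
    "quantify_hdr",
    "compute_heterogeneity",
    "indel_overlaps_window",
]

# SpCas9 cuts bluntly between the 17th and 18th protospacer bases, i.e.
# 3 nt 5' of the PAM.
CAS9_CUT_OFFSET = -3


@dataclass(frozen=True)
class CutWindow:
    """Amplicon interval (0-based half-open) where indels count as editing."""

    start: int
    end: int
    source: str = "guide_derived"  # "guide_derived" | "user_override"

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid cut window [{self.start}, {self.end})")


@dataclass
class HeterogeneitySummary:
    """Spectrum of read event-signatures (mosaicism indicator)."""

    n_signatures: int
    entropy_bits: float
    top_signatures: list  # [(signature string, frequency), ...]

    def to_dict(self) -> dict:
        return {
            "n_signatures": self.n_signatures,
            "entropy_bits": self.entropy_bits,
            "top_signatures": [list(t) for t in self.top_signatures],
        }


@dataclass
class EditingStats:
    """Quantified outcomes of one experiment."""

    reads_total: int = 0
    reads_edited: int = 0
    efficiency_pct: float = 0.0
    reads_frameshift: int = 0
    frameshift_pct: float = 0.0
    reads_hdr: int | None = None
    reads_nhej: int | None = None
    hdr_pct: float | None = None
    nhej_pct: float | None = None
    heterogeneity: HeterogeneitySummary | None = None
    filter_tallies: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "reads_total": self.reads_total,
            "reads_edited": self.reads_edited,
            "efficiency_pct": self.efficiency_pct,
            "reads_frameshift": self.reads_frameshift,
            "frameshift_pct": self.frameshift_pct,
            "hdr_pct": self.hdr_pct,
            "nhej_pct": self.nhej_pct,
            "filter_tallies": dict(self.filter_tallies),
        }
        if self.reads_hdr is not None:
            d["reads_hdr"] = self.reads_hdr
            d["reads_nhej"] = self.reads_nhej
        if self.heterogeneity is not None:
            d["heterogeneity"] = self.heterogeneity.to_dict()
        return d


def locate_cut_window(
    amplicon: str,
    guide_rna: str,
    flank: int = 5,
    cut_offset: int = CAS9_CUT_OFFSET,
    override: tuple[int, int] | None = None,
) -> CutWindow:
    """Cut window from the guide position, or a user override.

    For a forward-strand guide of length L at position p the cut coordinate
    is ``p + L + cut_offset`` (default offset -3, the blunt Cas9 cut);
    reverse-strand guides are mirrored.  The ±``flank`` window is clamped to
    the amplicon.  Errors if the guide is absent or not unique and no
    override is given.
    """
    if override is not None:
        start, end = override
        if not 0 <= start < end <= len(amplicon):
            raise ValueError(f"cut window override {override} outside amplicon")
        return CutWindow(start, end, source="user_override")
    amp = amplicon.upper()
    guide = guide_rna.upper()
    if not guide:
        raise ValueError("no guide RNA and no cut window override")
    fwd_hits = _find_all(amp, guide)
    rev_hits = _find_all(amp, reverse_complement(guide))
    if guide == reverse_complement(guide):  # palindromic guide: one strand
        rev_hits = []
    hits = [(p, "+") for p in fwd_hits] + [(p, "-") for p in rev_hits]
    if len(hits) != 1:
        raise ValueError(
            f"guide occurs {len(hits)} times in amplicon; need exactly one "
            f"occurrence or an explicit cut window"
        )
    p, strand = hits[0]
    if strand == "+":
        cut = p + len(guide) + cut_offset
    else:
        cut = p - cut_offset
    start = max(0, cut - flank)
    end = min(len(amplicon), cut + flank)
    return CutWindow(start, end, source="guide_derived")


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, start = [], 0
    while True:
        p = haystack.find(needle, start)
        if p < 0:
            return hits
        hits.append(p)
        start = p + 1


def indel_overlaps_window(ev: EditEvent, window: CutWindow) -> bool:
    """Half-open interval overlap; an insertion overlaps iff its anchor is
    inside the window."""
    if ev.type == "mismatch":
        return False
    if ev.type == "insertion":
        return window.start <= ev.start < window.end
    return ev.start < window.end and ev.end > window.start


def classify_frameshift(events: list[EditEvent]) -> bool:
    """True iff the net indel length over all retained indels is not a
    multiple of 3."""
    net = sum(
        len(ev.replacement) if ev.type == "insertion" else -ev.width
        for ev in events
        if ev.type in ("insertion", "deletion")
    )
    return net % 3 != 0


def compute_efficiency(table: EventTable, window: CutWindow) -> EditingStats:
    """Cut-window mutation efficiency and frameshift fraction.

    A read is edited iff >= 1 of its indel events overlaps the window;
    ``efficiency_pct = 100 * edited / total``.  Frameshift reads are the
    edited reads whose net indel length (over all their retained indels) is
    not a multiple of 3, so ``frameshift_pct <= efficiency_pct`` always.
    """
    if table.read_count_total == 0:
        raise ValueError(
            f"experiment {table.experiment_id!r}: no retained reads, "
            f"efficiency undefined"
        )
    edited = frameshift = 0
    for events in table.events_by_read().values():
        if any(indel_overlaps_window(ev, window) for ev in events):
            edited += 1
            if classify_frameshift(events):
                frameshift += 1
    total = table.read_count_total
    return EditingStats(
        reads_total=total,
        reads_edited=edited,
        efficiency_pct=100.0 * edited / total,
        reads_frameshift=frameshift,
        frameshift_pct=100.0 * frameshift / total,
    )


def hdr_expected_events(
    donor: str, amplicon: str, scoring: ScoringScheme | None = None
) -> list[EditEvent]:
    """Events a successful donor integration is expected to introduce.

    The donor template is aligned to the amplicon with the standard scoring
    and events are extracted exactly as for reads (so they are directly
    comparable by identity).  A donor that introduces only substitutions
    yields mismatch events -- the base-editor path.
    """
    aln = needleman_wunsch(donor, amplicon, scoring or ScoringScheme())
    expected = extract_events(aln, read_id="__donor__")
    if not expected:
        raise ValueError("donor is identical to the amplicon: no expected events")
    return expected


def quantify_hdr(
    table: EventTable,
    expected: list[EditEvent],
    window: CutWindow,
) -> EditingStats:
    """HDR and NHEJ fractions.

    A read is HDR iff it carries every expected donor event (exact identity
    matching, extra events tolerated); a non-HDR read is NHEJ iff it has at
    least one indel overlapping the cut window.  The two classes are
    disjoint by construction; percentages are of all retained reads.
    """
    if not expected:
        raise ValueError("expected event list is empty")
    if table.read_count_total == 0:
        raise ValueError("no retained reads, HDR quantification undefined")
    need = {ev.identity for ev in expected}
    hdr = nhej = 0
    for events in table.events_by_read().values():
        have = {ev.identity for ev in events}
        if need <= have:
            hdr += 1
        elif any(indel_overlaps_window(ev, window) for ev in events):
            nhej += 1
    total = table.read_count_total
    return EditingStats(
        reads_total=total,
        reads_hdr=hdr,
        reads_nhej=nhej,
        hdr_pct=100.0 * hdr / total,
        nhej_pct=100.0 * nhej / total,
    )


def signature_key(events: list[EditEvent]) -> str:
    """Canonical string for a read's event signature."""
    parts = [
        f"{ev.type[:3]}:{ev.start}-{ev.end}"
        + (f":{ev.replacement}" if ev.replacement else "")
        for ev in sorted(events, key=lambda e: (e.start, e.end, e.type))
    ]
    return ";".join(parts) if parts else "match"


def compute_heterogeneity(table: EventTable, top_n: int = 10) -> HeterogeneitySummary:
    """Signature spectrum and Shannon entropy (bits) of the read population.

    Reads without events form the reference ("match") signature.  High
    entropy indicates mosaic editing outcomes or unfiltered noise.
    """
    by_read = table.events_by_read()
    counts: dict[str, int] = {}
    for events in by_read.values():
        sig = signature_key(events)
        counts[sig] = counts.get(sig, 0) + 1
    n_match = table.read_count_total - len(by_read)
    if n_match > 0:
        counts["match"] = counts.get("match", 0) + n_match
    total = sum(counts.values())
    entropy = 0.0
    for c in counts.values():
        p = c / total
        entropy -= p * math.log2(p)
    top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    return HeterogeneitySummary(
        n_signatures=len(counts),
        entropy_bits=entropy,
        top_signatures=[(sig, c / total) for sig, c in top],
    )
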