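"""Global alignment of reads to their amplicon and edit-event extraction.

Reads from a nuclease experiment typically differ from the reference amplicon
by a single indel at the cut site (plus sequencing noise).  A standard
affine-gap Needleman--Wunsch aligner with a heavy gap-opening penalty and a
free gap extension therefore recovers the biologically expected alignment: it
strongly prefers one long indel over several fragmented ones, while free end
gaps let a read that covers only part of the amplicon align without spurious
terminal deletions.

The scoring defaults (match +5, mismatch -4, gap open -25, gap extension 0,
free end gaps) are the nuclease-optimised constants used throughout the
pipeline; a run of k gaps costs ``gap_open + k * gap_extension``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "ScoringScheme",
    "EditEvent",
    "Alignment",
    "AlignedRead",
    "needleman_wunsch",
    "extract_events",
    "left_normalize_events",
    "resolve_paired",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_NEG = -(10**9)

# traceback moves
_DIAG, _DEL, _INS = 0, 1, 2


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring constants.

    A gap run of length ``k`` costs ``gap_open + k * gap_extension``; with the
    defaults every internal gap run costs -25 regardless of its length, which
    penalises fragmented multi-indel alignments.  ``free_end_gaps`` makes
    terminal gap runs (in either sequence) cost nothing.
    """

    match: int = 5
    mismatch: int = -4
    gap_open: int = -25
    gap_extension: int = 0
    free_end_gaps: bool = True


@dataclass(frozen=True)
class EditEvent:
    """One atomic difference between a read and its amplicon.

    Coordinates are 0-based half-open on the amplicon forward strand.
    Insertions have ``start == end`` (the anchor is the reference position the
    inserted bases precede) and empty ``originally``; deletions have empty
    ``replacement``; mismatches are single-base.
    """

    type: str  # "insertion" | "deletion" | "mismatch"
    start: int
    end: int
    originally: str
    replacement: str
    read_id: str = ""

    def __post_init__(self):
        if self.type == "insertion":
            assert self.end == self.start and self.replacement and not self.originally
        elif self.type == "deletion":
            assert self.end > self.start and not self.replacement
        elif self.type == "mismatch":
            assert self.end == self.start + 1
            assert len(self.originally) == 1 and len(self.replacement) == 1
            assert self.originally != self.replacement
        else:  # pragma: no cover - guarded by callers
            raise ValueError(f"unknown event type {self.type!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def identity(self) -> tuple:
        """Key used for exact event matching (normalization, HDR)."""
        return (self.type, self.start, self.end, self.replacement)

    def with_read(self, read_id: str) -> "EditEvent":
        return replace(self, read_id=read_id)


@dataclass
class Alignment:
    """A pairwise global alignment of a read against an amplicon."""

    aligned_read: str
    aligned_ref: str
    score: int
    free_end_gaps: bool = True

    def __post_init__(self):
        assert len(self.aligned_read) == len(self.aligned_ref)


@dataclass
class AlignedRead:
    """A read (or consensus of a pair) with its events on amplicon coordinates.

    ``span`` is the half-open amplicon interval between the first and last
    non-end-gap alignment column, i.e. the region the read actually covers.
    """

    read_id: str
    experiment_id: str
    score_fwd: int
    score_rev: int | None = None
    events: list[EditEvent] = field(default_factory=list)
    span: tuple[int, int] = (0, 0)
    flags: set[str] = field(default_factory=set)


_BASE_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=False)
def _gotoh_fill(x, y, match, mismatch, gap_open, gap_ext, free_ends):
    """Fill the three Gotoh matrices.

    x = amplicon (rows), y = read (columns).  D holds states ending in a gap
    in the read (deletion from the amplicon), I states ending in a gap in the
    amplicon (insertion).
    """
    m = x.shape[0]
    n = y.shape[0]
    M = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    D = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    I = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    M[0, 0] = 0
    for i in range(1, m + 1):
        D[i, 0] = 0 if free_ends else gap_open + i * gap_ext
    for j in range(1, n + 1):
        I[0, j] = 0 if free_ends else gap_open + j * gap_ext
    for i in range(1, m + 1):
        xi = x[i - 1]
        for j in range(1, n + 1):
            s = match if xi == y[j - 1] else mismatch
            best_prev = M[i - 1, j - 1]
            if D[i - 1, j - 1] > best_prev:
                best_prev = D[i - 1, j - 1]
            if I[i - 1, j - 1] > best_prev:
                best_prev = I[i - 1, j - 1]
            M[i, j] = best_prev + s

            open_new = M[i - 1, j] + gap_open + gap_ext
            alt = I[i - 1, j] + gap_open + gap_ext
            if alt > open_new:
                open_new = alt
            ext = D[i - 1, j] + gap_ext
            D[i, j] = open_new if open_new > ext else ext

            open_new = M[i, j - 1] + gap_open + gap_ext
            alt = D[i, j - 1] + gap_open + gap_ext
            if alt > open_new:
                open_new = alt
            ext = I[i, j - 1] + gap_ext
            I[i, j] = open_new if open_new > ext else ext
    return M, D, I


def _best_state(M, D, I, i, j):
    """State with the maximal score at a cell; ties prefer M > D > I."""
    vals = (M[i, j], D[i, j], I[i, j])
    best = max(vals)
    return vals.index(best), best


def _traceback(M, D, I, x, y, scoring) -> tuple[list[int], int]:
    m, n = len(x), len(y)
    go, ge = scoring.gap_open, scoring.gap_extension
    if scoring.free_end_gaps:
        # best cell on the last row/column; prefer the corner, then longer
        # alignments (larger j, then larger i), strictly.
        end_i, end_j = m, n
        state, best = _best_state(M, D, I, m, n)
        for j in range(n - 1, -1, -1):
            s, v = _best_state(M, D, I, m, j)
            if v > best:
                end_i, end_j, state, best = m, j, s, v
        for i in range(m - 1, -1, -1):
            s, v = _best_state(M, D, I, i, n)
            if v > best:
                end_i, end_j, state, best = i, n, s, v
    else:
        end_i, end_j = m, n
        state, best = _best_state(M, D, I, m, n)

    moves: list[int] = []
    # trailing free end gaps
    moves.extend([_INS] * (n - end_j))
    moves.extend([_DEL] * (m - end_i))

    i, j = end_i, end_j
    while i > 0 or j > 0:
        if i == 0:
            moves.append(_INS)
            j -= 1
            continue
        if j == 0:
            moves.append(_DEL)
            i -= 1
            continue
        if state == _DIAG:
            moves.append(_DIAG)
            target = M[i, j] - (
                scoring.match if x[i - 1] == y[j - 1] else scoring.mismatch
            )
            i -= 1
            j -= 1
            for cand, mat in ((_DIAG, M), (_DEL, D), (_INS, I)):
                if mat[i, j] == target:
                    state = cand
                    break
        elif state == _DEL:
            moves.append(_DEL)
            target = D[i, j]
            i -= 1
            if M[i, j] + go + ge == target:
                state = _DIAG
            elif D[i, j] + ge == target:
                state = _DEL
            else:
                state = _INS
        else:
            moves.append(_INS)
            target = I[i, j]
            j -= 1
            if M[i, j] + go + ge == target:
                state = _DIAG
            elif I[i, j] + ge == target:
                state = _INS
            else:
                state = _DEL
    moves.reverse()
    return moves, int(best)


def needleman_wunsch(
    read_seq: str, amplicon: str, scoring: ScoringScheme | None = None
) -> Alignment:
    """Globally align a read to its amplicon.

    Returns a maximum-score alignment under ``scoring``; with free end gaps,
    terminal gap runs in either sequence cost nothing.  Traceback ties prefer
    diagonal over deletion over insertion, which combined with the
    left-normalization in :func:`extract_events` makes event placement
    deterministic.
    """
    if not read_seq or not amplicon:
        raise ValueError("cannot align empty sequences")
    scoring = scoring or ScoringScheme()
    x = _encode(amplicon)
    y = _encode(read_seq)
    M, D, I = _gotoh_fill(
        x,
        y,
        scoring.match,
        scoring.mismatch,
        scoring.gap_open,
        scoring.gap_extension,
        scoring.free_end_gaps,
    )
    moves, score = _traceback(M, D, I, amplicon, read_seq, scoring)
    ar, aref = [], []
    i = j = 0
    for mv in moves:
        if mv == _DIAG:
            ar.append(read_seq[j])
            aref.append(amplicon[i])
            i += 1
            j += 1
        elif mv == _DEL:
            ar.append("-")
            aref.append(amplicon[i])
            i += 1
        else:
            ar.append(read_seq[j])
            aref.append("-")
            j += 1
    return Alignment(
        "".join(ar), "".join(aref), score, free_end_gaps=scoring.free_end_gaps
    )


def _terminal_run(columns: list[tuple[str, str]], reverse: bool) -> int:
    """Length of the leading (or trailing) uniform gap run."""
    it = reversed(columns) if reverse else iter(columns)
    kind = None
    k = 0
    for r, q in it:
        if r == "-":
            this = "ins"
        elif q == "-":
            this = "del"
        else:
            break
        if kind is None:
            kind = this
        elif this != kind:
            break
        k += 1
    return k


def extract_events(alignment: Alignment, read_id: str = "") -> list[EditEvent]:
    """Turn an alignment into left-normalized edit events.

    Contiguous gap runs become one deletion/insertion event each; substituted
    columns become single-base mismatch events.  When the alignment was made
    with free end gaps, the terminal gap runs are the unsequenced flanks of
    the read and yield no events.  Indels are shifted to their leftmost
    equivalent placement so that identical edits always get identical
    coordinates.
    """
    cols = list(zip(alignment.aligned_ref, alignment.aligned_read))
    lead = tail = 0
    if alignment.free_end_gaps:
        lead = _terminal_run(cols, reverse=False)
        tail = _terminal_run(cols, reverse=True)
        if lead == len(cols):  # degenerate: all-gap alignment
            tail = 0
    ref_pos = sum(1 for r, _ in cols[:lead] if r != "-")
    span_start = ref_pos
    body = cols[lead : len(cols) - tail]

    events: list[EditEvent] = []
    i = 0
    while i < len(body):
        r, q = body[i]
        if q == "-":  # deletion from the amplicon
            j = i
            while j < len(body) and body[j][1] == "-":
                j += 1
            width = j - i
            events.append(
                EditEvent(
                    "deletion",
                    ref_pos,
                    ref_pos + width,
                    "".join(c[0] for c in body[i:j]),
                    "",
                    read_id,
                )
            )
            ref_pos += width
            i = j
        elif r == "-":  # insertion into the read
            j = i
            while j < len(body) and body[j][0] == "-":
                j += 1
            events.append(
                EditEvent(
                    "insertion",
                    ref_pos,
                    ref_pos,
                    "",
                    "".join(c[1] for c in body[i:j]),
                    read_id,
                )
            )
            i = j
        else:
            if r != q:
                events.append(
                    EditEvent("mismatch", ref_pos, ref_pos + 1, r, q, read_id)
                )
            ref_pos += 1
            i += 1
    # strip ref gaps from deletion "originally" (they cannot occur) and
    # left-normalize against the reference
    ref = alignment.aligned_ref.replace("-", "")
    return left_normalize_events(events, ref, span_start)


def left_normalize_events(
    events: list[EditEvent], ref: str, span_start: int = 0
) -> list[EditEvent]:
    """Shift indels to their leftmost equivalent placement.

    An indel may slide left through a repeat (e.g. a deletion inside a
    homopolymer) without changing the implied read sequence; the leftmost
    placement is taken as canonical.  Events never slide past another event
    or past the start of the sequenced span.
    """
    out: list[EditEvent] = []
    barrier = span_start
    for ev in sorted(events, key=lambda e: (e.start, e.end)):
        if ev.type == "deletion":
            s, e = ev.start, ev.end
            while s - 1 >= barrier and ref[s - 1] == ref[e - 1]:
                s -= 1
                e -= 1
            if s != ev.start:
                ev = EditEvent("deletion", s, e, ref[s:e], "", ev.read_id)
            barrier = ev.end
        elif ev.type == "insertion":
            s = ev.start
            seq = ev.replacement
            while s - 1 >= barrier and ref[s - 1] == seq[-1]:
                seq = ref[s - 1] + seq[:-1]
                s -= 1
            if s != ev.start:
                ev = EditEvent("insertion", s, s, "", seq, ev.read_id)
            barrier = ev.start
        else:
            barrier = ev.end
        out.append(ev)
    out.sort(key=lambda e: (e.start, e.end, e.type, e.replacement))
    return out


def _overlaps(ev: EditEvent, start: int, end: int) -> bool:
    if ev.type == "insertion":
        return start <= ev.start < end
    return ev.start < end and ev.end > start


def resolve_paired(fwd: AlignedRead, rev: AlignedRead) -> list[EditEvent]:
    """Consensus event list for a forward/reverse mate pair.

    Both mates are on amplicon-forward coordinates (the reverse mate is
    reverse-complemented before alignment).  Within the region covered by
    both mates, the mate with the higher alignment score decides any
    disagreement -- including reporting no event where the other mate saw
    one; events agreed by both are kept once.  Outside the overlap each mate
    contributes its own events.
    """
    if fwd.experiment_id != rev.experiment_id:
        raise ValueError(
            f"mates assigned to different experiments: "
            f"{fwd.experiment_id!r} vs {rev.experiment_id!r}"
        )
    ov_start = max(fwd.span[0], rev.span[0])
    ov_end = min(fwd.span[1], rev.span[1])
    winner, loser = (fwd, rev) if fwd.score_fwd >= rev.score_fwd else (rev, fwd)

    seen: set[tuple] = set()
    consensus: list[EditEvent] = []

    def _add(ev: EditEvent) -> None:
        if ev.identity not in seen:
            seen.add(ev.identity)
            consensus.append(ev)

    if ov_start < ov_end:
        for ev in winner.events:
            if _overlaps(ev, ov_start, ov_end):
                _add(ev)
    for mate in (fwd, rev):
        for ev in mate.events:
            if not (ov_start < ov_end and _overlaps(ev, ov_start, ov_end)):
                _add(ev)
    consensus.sort(key=lambda e: (e.start, e.end, e.type, e.replacement))
    return consensus
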