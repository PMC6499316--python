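"""Independent oracles and small utilities shared by the test suite."""

from __future__ import annotations

import numpy as np

from editscan.align import EditEvent, ScoringScheme

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def oracle_score(x: str, y: str, scoring: ScoringScheme) -> int:
    """Best alignment score by exhaustive enumeration of all alignments.

    Independent of the DP implementation: recursively enumerates every
    monotone sequence of (diagonal | gap-in-y | gap-in-x) moves and scores
    it under the run-based gap model -- a maximal gap run of length k costs
    gap_open + k * gap_extension, except that with free end gaps the first
    and last run of the alignment cost nothing when they are gap runs.
    Feasible for sequences up to ~8 nt.
    """
    m, n = len(x), len(y)
    ma, mi = scoring.match, scoring.mismatch
    go, ge = scoring.gap_open, scoring.gap_extension
    free = scoring.free_end_gaps
    best = -(10**9)

    # state: 0 = not inside a gap run, 1 = gap consuming x (deletion from y's
    # point of view), 2 = gap consuming y
    def rec(i, j, state, score, run_len, leading):
        nonlocal best

        def close_cost():
            if state == 0:
                return 0
            if free and leading:
                return 0
            return go + ge * run_len

        if i == m and j == n:
            total = score + (0 if (free and state != 0) else close_cost())
            if total > best:
                best = total
            return
        if i < m and j < n:
            s = ma if x[i] == y[j] else mi
            rec(i + 1, j + 1, 0, score + close_cost() + s, 0, False)
        if i < m:
            if state == 1:
                rec(i + 1, j, 1, score, run_len + 1, leading)
            else:
                rec(i + 1, j, 1, score + close_cost(), 1, i == 0 and j == 0)
        if j < n:
            if state == 2:
                rec(i, j + 1, 2, score, run_len + 1, leading)
            else:
                rec(i, j + 1, 2, score + close_cost(), 1, i == 0 and j == 0)

    rec(0, 0, 0, 0, 0, False)
    return best


def apply_events(ref: str, events: list[EditEvent], span: tuple[int, int]) -> str:
    """Reconstruct the read implied by events over the sequenced span."""
    s0, s1 = span
    out = []
    pos = s0
    for ev in sorted(events, key=lambda e: (e.start, e.end)):
        out.append(ref[pos : ev.start])
        if ev.type == "deletion":
            pos = ev.end
        elif ev.type == "insertion":
            out.append(ev.replacement)
            pos = ev.start
        else:
            out.append(ev.replacement)
            pos = ev.end
    out.append(ref[pos:s1])
    return "".join(out)


def pooled_efficiency(results) -> float:
    """Pooled editing efficiency (%) over a pipeline result dict."""
    total = sum(r.stats.reads_total for r in results.values())
    edited = sum(r.stats.reads_edited for r in results.values())
    return 100.0 * edited / total
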