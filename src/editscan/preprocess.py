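"""Read quality filtering and primer-based experiment assignment.

In amplicon protocols sequencing starts at the primer, so a read is assigned
to an experiment by matching the experiment's primer at the read 5' end
(Hamming matching, no indels, default up to two mismatches).  Reads matching
zero or several experiments are reported as unassigned rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .config_io import ConfigError, ExperimentRecord, SequencedRead

__all__ = [
    "QualityThresholds",
    "AssignmentResult",
    "AssignmentTally",
    "quality_filter",
    "match_primer",
    "assign_reads",
]

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class QualityThresholds:
    """Read-level quality filters.

    Defaults: mean Phred >= 30, no per-base minimum, ambiguous bases
    (non-ACGT) rejected.
    """

    min_avg_phred: float = 30.0
    min_base_phred: float = 0.0
    allow_ambiguous: bool = False

    def __post_init__(self):
        if self.min_avg_phred < 0 or self.min_base_phred < 0:
            raise ValueError("quality thresholds must be >= 0")


@dataclass
class AssignmentResult:
    read_id: str
    status: str  # "assigned" | "unassigned" | "quality_rejected"
    experiment_id: str | None = None
    fwd_primer_pos: int | None = None
    rev_primer_pos: int | None = None

    def __post_init__(self):
        assert (self.status == "assigned") == (self.experiment_id is not None)


@dataclass
class AssignmentTally:
    total: int = 0
    assigned: int = 0
    unassigned: int = 0
    quality_rejected: int = 0
    per_experiment: dict = field(default_factory=dict)

    def conserved(self) -> bool:
        return self.assigned + self.unassigned + self.quality_rejected == self.total


def quality_filter(read: SequencedRead, thresholds: QualityThresholds) -> bool:
    """True iff the read passes all quality filters."""
    if not thresholds.allow_ambiguous and (set(read.sequence) - _ACGT):
        return False
    if not read.qualities:
        return False
    if sum(read.qualities) / len(read.qualities) < thresholds.min_avg_phred:
        return False
    if min(read.qualities) < thresholds.min_base_phred:
        return False
    return True


def match_primer(
    sequence: str,
    primer: str,
    max_mismatches: int = 2,
    anchored: bool = True,
    scan_window: int = 0,
) -> int | None:
    """Leftmost position where the primer matches within ``max_mismatches``.

    Hamming matching only (no indels).  With ``anchored`` (the default for
    read assignment) only position 0 is considered; ``scan_window`` > 0
    relaxes this to the first ``scan_window`` start positions.  Returns the
    position or None.
    """
    if not primer:
        raise ValueError("primer must be nonempty")
    n, k = len(sequence), len(primer)
    last = 0 if anchored else min(scan_window, n - k)
    for p in range(0, last + 1):
        if p + k > n:
            break
        mm = 0
        for a, b in zip(sequence[p : p + k], primer):
            if a != b:
                mm += 1
                if mm > max_mismatches:
                    break
        if mm <= max_mismatches:
            return p
    return None


def _check_distinct_primers(experiments: list[ExperimentRecord]) -> None:
    seen: dict[tuple[str, str], str] = {}
    for exp in experiments:
        key = (exp.forward_primer, exp.reverse_primer)
        if key in seen:
            raise ConfigError(
                f"experiments {seen[key]!r} and {exp.id!r} share an identical "
                f"primer pair within one barcode"
            )
        seen[key] = exp.id


def assign_reads(
    read_pairs: Iterable[tuple[SequencedRead, SequencedRead | None]],
    experiments: list[ExperimentRecord],
    thresholds: QualityThresholds | None = None,
    max_mismatches: int = 2,
    anchored: bool = True,
    scan_window: int = 0,
) -> tuple[dict, AssignmentTally, list[AssignmentResult]]:
    """Assign quality-passing read (pairs) to experiments by primer matching.

    A pair is assigned when exactly one experiment's forward primer matches
    the forward read 5' end and (for paired data) its reverse primer matches
    the reverse read 5' end.  Zero or multiple candidates leave the read
    unassigned.  Returns (reads per experiment id, tally, per-read results);
    the tally conserves the input count across the three categories.
    """
    thresholds = thresholds or QualityThresholds()
    _check_distinct_primers(experiments)
    by_exp: dict[str, list] = {e.id: [] for e in experiments}
    tally = AssignmentTally(per_experiment={e.id: 0 for e in experiments})
    results: list[AssignmentResult] = []
    for fwd, rev in read_pairs:
        tally.total += 1
        ok = quality_filter(fwd, thresholds) and (
            rev is None or quality_filter(rev, thresholds)
        )
        if not ok:
            tally.quality_rejected += 1
            results.append(AssignmentResult(fwd.read_id, "quality_rejected"))
            continue
        hits = []
        for exp in experiments:
            fpos = match_primer(
                fwd.sequence, exp.forward_primer, max_mismatches, anchored,
                scan_window,
            )
            if fpos is None:
                continue
            rpos = None
            if rev is not None:
                rpos = match_primer(
                    rev.sequence, exp.reverse_primer, max_mismatches, anchored,
                    scan_window,
                )
                if rpos is None:
                    continue
            hits.append((exp.id, fpos, rpos))
        if len(hits) == 1:
            exp_id, fpos, rpos = hits[0]
            by_exp[exp_id].append((fwd, rev))
            tally.assigned += 1
            tally.per_experiment[exp_id] += 1
            results.append(
                AssignmentResult(fwd.read_id, "assigned", exp_id, fpos, rpos)
            )
        else:
            tally.unassigned += 1
            results.append(AssignmentResult(fwd.read_id, "unassigned"))
    return by_exp, tally, results
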