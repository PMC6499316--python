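"""Aggregation of editing statistics and filtering summaries.

Statistics can be pooled at any configuration level (identifier, barcode,
guide, amplicon, group, or a single run-wide summary).  Pooling always sums
read counts and recomputes percentages from the summed counts -- percentages
are never averaged, so a large experiment is not diluted by a small one.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config_io import ExperimentRecord
from .normalize_filter import EventTable
from .quantify import EditingStats, classify_frameshift, signature_key

__all__ = [
    "AGGREGATION_LEVELS",
    "aggregate",
    "top_reads_summary",
    "filter_report",
    "FilterTally",
]

AGGREGATION_LEVELS = ("identifier", "barcode", "guide", "amplicon", "group", "summary")

_LEVEL_KEY = {
    "identifier": lambda r: r.id,
    "barcode": lambda r: r.barcode,
    "guide": lambda r: r.guide_rna,
    "amplicon": lambda r: r.amplicon,
    "group": lambda r: r.group,
    "summary": lambda r: "all",
}

_COUNT_FIELDS = ("reads_total", "reads_edited", "reads_frameshift")


def aggregate(
    stats: list[tuple[ExperimentRecord, EditingStats]], level: str
) -> pd.DataFrame:
    """Pool per-experiment statistics at a configuration level.

    Read counts are summed within each key; efficiency/frameshift (and HDR,
    where every member reports it) percentages are recomputed from the summed
    counts.  Output rows are sorted by key.
    """
    if level not in AGGREGATION_LEVELS:
        raise ValueError(
            f"unknown aggregation level {level!r}; expected one of "
            f"{AGGREGATION_LEVELS}"
        )
    if not stats:
        raise ValueError("no statistics to aggregate")
    keyfn = _LEVEL_KEY[level]
    groups: dict[str, dict] = {}
    for rec, st in stats:
        g = groups.setdefault(
            keyfn(rec),
            {f: 0 for f in _COUNT_FIELDS}
            | {"n_experiments": 0, "reads_hdr": 0, "reads_nhej": 0, "has_hdr": True},
        )
        g["n_experiments"] += 1
        for f in _COUNT_FIELDS:
            g[f] += getattr(st, f)
        if st.reads_hdr is None:
            g["has_hdr"] = False
        else:
            g["reads_hdr"] += st.reads_hdr
            g["reads_nhej"] += st.reads_nhej
    rows = []
    for key in sorted(groups):
        g = groups[key]
        total = g["reads_total"]
        row = {
            level: key,
            "n_experiments": g["n_experiments"],
            "reads_total": total,
            "reads_edited": g["reads_edited"],
            "efficiency_pct": 100.0 * g["reads_edited"] / total if total else 0.0,
            "reads_frameshift": g["reads_frameshift"],
            "frameshift_pct": 100.0 * g["reads_frameshift"] / total if total else 0.0,
        }
        if g["has_hdr"]:
            row["hdr_pct"] = 100.0 * g["reads_hdr"] / total if total else 0.0
            row["nhej_pct"] = 100.0 * g["reads_nhej"] / total if total else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def top_reads_summary(table: EventTable, n: int = 10) -> pd.DataFrame:
    """The n most abundant read signatures with frequency, count, summed
    indel size and frameshift flag.  Ties in count break lexically by
    signature so output is deterministic."""
    by_read = table.events_by_read()
    sigs: dict[str, dict] = {}
    for events in by_read.values():
        key = signature_key(events)
        entry = sigs.setdefault(
            key,
            {
                "count": 0,
                "indel_size": sum(
                    len(e.replacement) if e.type == "insertion" else e.width
                    for e in events
                    if e.type != "mismatch"
                ),
                "frameshift": classify_frameshift(events),
            },
        )
        entry["count"] += 1
    n_match = table.read_count_total - len(by_read)
    if n_match > 0:
        entry = sigs.setdefault(
            "match", {"count": 0, "indel_size": 0, "frameshift": False}
        )
        entry["count"] += n_match
    total = table.read_count_total or 1
    ordered = sorted(sigs.items(), key=lambda kv: (-kv[1]["count"], kv[0]))[:n]
    return pd.DataFrame(
        [
            {
                "signature": key,
                "count": v["count"],
                "frequency_pct": 100.0 * v["count"] / total,
                "indel_size": v["indel_size"],
                "frameshift": v["frameshift"],
            }
            for key, v in ordered
        ]
    )


@dataclass
class FilterTally:
    """Per-experiment (or per file-group) read bookkeeping."""

    id: str
    input_reads: int = 0
    quality_rejected: int = 0
    unassigned: int = 0
    primer_dimer: int = 0
    artifact: int = 0
    retained: int = 0


def filter_report(tallies: list[FilterTally]) -> pd.DataFrame:
    """Tabulate the impact of every filtering stage, with a TOTAL row.

    Raises if counts are not conserved: over the whole run, retained +
    flagged + unassigned + quality-rejected must equal the input reads.
    """
    rows = [t.__dict__ for t in sorted(tallies, key=lambda t: t.id)]
    df = pd.DataFrame(rows)
    total = {"id": "TOTAL"}
    for col in df.columns[1:]:
        total[col] = int(df[col].sum())
    accounted = (
        total["quality_rejected"]
        + total["unassigned"]
        + total["primer_dimer"]
        + total["artifact"]
        + total["retained"]
    )
    if accounted != total["input_reads"]:
        raise ValueError(
            f"filter tallies not conserved: {accounted} accounted vs "
            f"{total['input_reads']} input reads"
        )
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)
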