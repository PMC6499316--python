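"""Experiment configuration parsing, FASTQ streaming and table export.

An amplicon-sequencing run is described by one configuration table with one
row per experiment: the amplicon reference, the primer pair used to assign
reads, the guide RNA (or an explicit cut-window override for TALEN/nickase
designs), an optional HDR donor template, a group label, a control flag and
the FASTQ file paths.  Controls are ordinary rows flagged ``Control``; a
treatment is linked to the control(s) sharing its amplicon and barcode, or to
an explicit ``Control_ID``.
"""

from __future__ import annotations

import csv
import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from .align import reverse_complement

__all__ = [
    "ExperimentRecord",
    "SequencedRead",
    "ConfigError",
    "FastqError",
    "REQUIRED_COLUMNS",
    "load_experiment_config",
    "write_experiment_config",
    "read_fastq",
    "read_fastq_pairs",
    "write_fastq",
    "write_event_table",
    "write_stats_json",
]

REQUIRED_COLUMNS = [
    "ID",
    "Barcode",
    "Forward_Reads_File",
    "Reverse_Reads_File",
    "Group",
    "Control",
    "guideRNA",
    "Forward_Primer",
    "Reverse_Primer",
    "Amplicon",
    "Donor",
]

_TRUE = {"1", "true", "yes", "t", "y"}
_FALSE = {"0", "false", "no", "f", "n", ""}


class ConfigError(ValueError):
    """Invalid experiment configuration."""


class FastqError(ValueError):
    """Malformed FASTQ input."""


@dataclass
class ExperimentRecord:
    """One configured amplicon experiment."""

    id: str
    barcode: str
    forward_primer: str
    reverse_primer: str
    guide_rna: str
    amplicon: str
    donor: str | None = None
    group: str = ""
    is_control: bool = False
    control_id: str | None = None
    fastq_fwd: str = ""
    fastq_rev: str | None = None
    cut_window_override: tuple[int, int] | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def paired(self) -> bool:
        return bool(self.fastq_rev)


@dataclass
class SequencedRead:
    """A single sequenced read with Phred+33-decoded qualities."""

    read_id: str
    sequence: str
    qualities: list[int]
    mate: str = "single"  # "forward" | "reverse" | "single"

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise FastqError(
                f"read {self.read_id!r}: sequence/quality length mismatch"
            )


def _count_occurrences(amplicon: str, guide: str) -> int:
    """Occurrences of a guide on either strand of the amplicon."""
    amp = amplicon.upper()
    n = 0
    for probe in {guide.upper(), reverse_complement(guide.upper())}:
        start = 0
        while True:
            p = amp.find(probe, start)
            if p < 0:
                break
            n += 1
            start = p + 1
    return n


def _parse_window(text: str, row_no: int) -> tuple[int, int]:
    try:
        a, b = text.split(":")
        start, end = int(a), int(b)
    except ValueError as exc:
        raise ConfigError(
            f"row {row_no}: Cut_Window must be 'start:end', got {text!r}"
        ) from exc
    if not 0 <= start < end:
        raise ConfigError(f"row {row_no}: invalid Cut_Window {text!r}")
    return start, end


def load_experiment_config(
    path: str | Path, dialect: str = "csv"
) -> list[ExperimentRecord]:
    """Parse and validate an experiment configuration table.

    Raises :class:`ConfigError` naming the offending column or row on missing
    columns, duplicate identifiers, or a guide RNA that does not occur exactly
    once in its amplicon (on either strand) without a ``Cut_Window`` override.
    """
    path = Path(path)
    delim = {"csv": ",", "tsv": "\t"}[dialect]
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise ConfigError(f"missing required column(s): {', '.join(missing)}")
        extra_cols = [c for c in header if c not in REQUIRED_COLUMNS]
        records: list[ExperimentRecord] = []
        errors: list[str] = []
        seen_ids: set[str] = set()
        for row_no, row in enumerate(reader, start=2):  # 1 = header line
            rid = (row["ID"] or "").strip()
            if not rid:
                errors.append(f"row {row_no}: empty ID")
                continue
            if rid in seen_ids:
                errors.append(f"row {row_no}: duplicate ID {rid!r}")
                continue
            seen_ids.add(rid)
            amplicon = (row["Amplicon"] or "").strip().upper()
            guide = (row["guideRNA"] or "").strip().upper()
            fwd_primer = (row["Forward_Primer"] or "").strip().upper()
            rev_primer = (row["Reverse_Primer"] or "").strip().upper()
            window = None
            window_text = (row.get("Cut_Window") or "").strip()
            if window_text:
                try:
                    window = _parse_window(window_text, row_no)
                except ConfigError as exc:
                    errors.append(str(exc))
                    continue
            if not amplicon:
                errors.append(f"row {row_no} ({rid}): empty Amplicon")
                continue
            if fwd_primer and amplicon.find(fwd_primer) != 0:
                errors.append(
                    f"row {row_no} ({rid}): Forward_Primer is not a prefix of "
                    f"the amplicon"
                )
                continue
            if rev_primer and not amplicon.endswith(
                reverse_complement(rev_primer)
            ):
                errors.append(
                    f"row {row_no} ({rid}): reverse complement of "
                    f"Reverse_Primer not found at the amplicon 3' end"
                )
                continue
            if guide and window is None:
                n_occ = _count_occurrences(amplicon, guide)
                if n_occ == 0:
                    errors.append(
                        f"row {row_no} ({rid}): guideRNA not found in amplicon "
                        f"and no Cut_Window override given"
                    )
                    continue
                if n_occ > 1:
                    errors.append(
                        f"row {row_no} ({rid}): guideRNA occurs {n_occ} times "
                        f"in amplicon; give a Cut_Window override"
                    )
                    continue
            if not guide and window is None:
                errors.append(
                    f"row {row_no} ({rid}): empty guideRNA requires a "
                    f"Cut_Window override"
                )
                continue
            control_raw = (row["Control"] or "").strip().lower()
            if control_raw in _TRUE:
                is_control = True
            elif control_raw in _FALSE:
                is_control = False
            else:
                errors.append(
                    f"row {row_no} ({rid}): Control must be boolean-like, "
                    f"got {row['Control']!r}"
                )
                continue
            donor = (row["Donor"] or "").strip().upper() or None
            records.append(
                ExperimentRecord(
                    id=rid,
                    barcode=(row["Barcode"] or "").strip(),
                    forward_primer=fwd_primer,
                    reverse_primer=rev_primer,
                    guide_rna=guide,
                    amplicon=amplicon,
                    donor=donor,
                    group=(row["Group"] or "").strip(),
                    is_control=is_control,
                    control_id=(row.get("Control_ID") or "").strip() or None,
                    fastq_fwd=(row["Forward_Reads_File"] or "").strip(),
                    fastq_rev=(row["Reverse_Reads_File"] or "").strip() or None,
                    cut_window_override=window,
                    metadata={
                        c: row[c]
                        for c in extra_cols
                        if c not in ("Control_ID", "Cut_Window")
                    },
                )
            )
    if errors:
        raise ConfigError("; ".join(errors))
    _link_controls(records)
    return records


def _link_controls(records: list[ExperimentRecord]) -> None:
    """Fill ``control_id`` for treatments lacking an explicit link.

    A treatment is matched to the control rows sharing its (amplicon,
    barcode); when exactly one matches, its id is recorded.  Downstream
    normalization always uses the union of all matching controls.
    """
    by_key: dict[tuple[str, str], list[str]] = {}
    ids = {r.id for r in records}
    for r in records:
        if r.is_control:
            by_key.setdefault((r.amplicon, r.barcode), []).append(r.id)
    for r in records:
        if r.is_control:
            continue
        if r.control_id is not None:
            if r.control_id not in ids:
                raise ConfigError(
                    f"experiment {r.id!r}: Control_ID {r.control_id!r} does "
                    f"not name a configured experiment"
                )
            continue
        matches = by_key.get((r.amplicon, r.barcode), [])
        if len(matches) == 1:
            r.control_id = matches[0]


def controls_for(
    record: ExperimentRecord, records: Iterable[ExperimentRecord]
) -> list[ExperimentRecord]:
    """All control records a treatment is normalized against."""
    if record.control_id is not None:
        return [r for r in records if r.id == record.control_id]
    return [
        r
        for r in records
        if r.is_control
        and r.amplicon == record.amplicon
        and r.barcode == record.barcode
    ]


def write_experiment_config(
    records: Iterable[ExperimentRecord], path: str | Path
) -> None:
    """Write records back to the CSV schema read by ``load_experiment_config``."""
    records = list(records)
    extra = sorted({k for r in records for k in r.metadata})
    cols = REQUIRED_COLUMNS + ["Control_ID", "Cut_Window"] + extra
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for r in records:
            window = (
                f"{r.cut_window_override[0]}:{r.cut_window_override[1]}"
                if r.cut_window_override
                else ""
            )
            writer.writerow(
                [
                    r.id,
                    r.barcode,
                    r.fastq_fwd,
                    r.fastq_rev or "",
                    r.group,
                    "1" if r.is_control else "0",
                    r.guide_rna,
                    r.forward_primer,
                    r.reverse_primer,
                    r.amplicon,
                    r.donor or "",
                    r.control_id or "",
                    window,
                ]
                + [r.metadata.get(k, "") for k in extra]
            )


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq(path: str | Path, mate: str = "single") -> Iterator[SequencedRead]:
    """Stream Phred+33 FASTQ records (plain or gzip-compressed)."""
    path = Path(path)
    idx = -1
    with _open_maybe_gzip(path) as fh:
        try:
            for idx, rec in enumerate(SeqIO.parse(fh, "fastq")):
                yield SequencedRead(
                    read_id=rec.id,
                    sequence=str(rec.seq).upper(),
                    qualities=list(rec.letter_annotations["phred_quality"]),
                    mate=mate,
                )
        except ValueError as exc:
            raise FastqError(f"{path}: malformed FASTQ near record {idx}: {exc}")


def read_fastq_pairs(
    fwd_path: str | Path, rev_path: str | Path | None
) -> Iterator[tuple[SequencedRead, SequencedRead | None]]:
    """Pair forward/reverse files positionally; single-end yields (read, None)."""
    if rev_path is None:
        for read in read_fastq(fwd_path, mate="single"):
            yield read, None
        return
    fwd_it = read_fastq(fwd_path, mate="forward")
    rev_it = read_fastq(rev_path, mate="reverse")
    while True:
        fwd = next(fwd_it, None)
        rev = next(rev_it, None)
        if fwd is None and rev is None:
            return
        if fwd is None or rev is None:
            raise FastqError(
                f"paired files {fwd_path} / {rev_path} have different record "
                f"counts"
            )
        yield fwd, rev


def write_fastq(reads: Iterable[SequencedRead], path: str | Path) -> None:
    """Write Phred+33 FASTQ; gzip-compressed when the path ends in .gz.

    Gzip output is written with a zeroed header timestamp so identical reads
    always produce byte-identical files (a reproducibility contract relied on
    by the simulator).
    """
    path = Path(path)
    chunks = []
    for read in reads:
        quals = "".join(chr(q + 33) for q in read.qualities)
        chunks.append(f"@{read.read_id}\n{read.sequence}\n+\n{quals}\n")
    payload = "".join(chunks).encode("ascii")
    if str(path).endswith(".gz"):
        with open(path, "wb") as raw:
            with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0, filename="") as gz:
                gz.write(payload)
    else:
        with open(path, "wb") as fh:
            fh.write(payload)


_EVENT_COLUMNS = [
    "seqnames",
    "start",
    "end",
    "width",
    "strand",
    "originally",
    "replacement",
    "type",
    "read_id",
    "counts",
    "score",
]


def write_event_table(events, path: str | Path) -> None:
    """Export an event table as TSV with 1-based inclusive coordinates.

    Deletions/mismatches of internal span [s, e) are exported as start s+1,
    end e.  Insertions (zero-width internally) are anchored at the base
    immediately left of the insertion point and exported with width 1.
    """
    rows = []
    scores = getattr(events, "read_scores", {})
    for ev in events.events:
        if ev.type == "insertion":
            start = ev.start  # 1-based coordinate of the base to the left
            end = ev.start
            width = 1 if ev.start > 0 else 0
        else:
            start = ev.start + 1
            end = ev.end
            width = ev.end - ev.start
        rows.append(
            {
                "seqnames": events.experiment_id,
                "start": start,
                "end": end,
                "width": width,
                "strand": "+",
                "originally": ev.originally,
                "replacement": ev.replacement,
                "type": ev.type,
                "read_id": ev.read_id,
                "counts": 1,
                "score": scores.get(ev.read_id, ""),
            }
        )
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(path, sep="\t", index=False)


def write_stats_json(stats_by_id: dict, path: str | Path) -> None:
    """Serialize per-experiment EditingStats dictionaries to JSON."""
    payload = {
        k: (v.to_dict() if hasattr(v, "to_dict") else v)
        for k, v in stats_by_id.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
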