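"""End-to-end orchestration: FASTQ -> alignment -> filtering -> statistics.

The pipeline mirrors a wet-lab analysis: reads are quality-filtered and
assigned to experiments by primer matching; each read (pair) is globally
aligned to its amplicon; primer-dimer and off-target/artifact reads are
flagged out; controls are processed identically and used for event-level
normalization; finally cut-window efficiency, frameshift fraction,
heterogeneity and (when a donor is configured) HDR/NHEJ rates are computed
and exported as TSV/JSON.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import report as report_mod
from .align import (
    AlignedRead,
    ScoringScheme,
    extract_events,
    needleman_wunsch,
    resolve_paired,
    reverse_complement,
)
from .config_io import (
    ExperimentRecord,
    controls_for,
    load_experiment_config,
    read_fastq_pairs,
    write_event_table,
    write_stats_json,
)
from .normalize_filter import (
    ArtifactModel,
    EventTable,
    detect_primer_dimer,
    flag_artifact_reads,
    merge_event_tables,
    normalize_with_control,
)
from .preprocess import QualityThresholds, assign_reads
from .quantify import (
    EditingStats,
    compute_efficiency,
    compute_heterogeneity,
    hdr_expected_events,
    locate_cut_window,
    quantify_hdr,
)

__all__ = ["PipelineParams", "ExperimentResult", "run_pipeline", "align_experiment"]


@dataclass(frozen=True)
class PipelineParams:
    """All tunable knobs of one pipeline run."""

    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    quality: QualityThresholds = field(default_factory=QualityThresholds)
    primer_mismatches: int = 2
    primer_scan_window: int = 0
    dimer_buffer: int = 30
    artifact: ArtifactModel = field(default_factory=ArtifactModel)
    control_noise_threshold: float = 0.01
    normalization_slack: int = 0
    cut_flank: int = 5
    cut_offset: int = -3


@dataclass
class ExperimentResult:
    record: ExperimentRecord
    raw_table: EventTable
    table: EventTable  # post-normalization
    stats: EditingStats
    tally: report_mod.FilterTally


def _align_one(seq: str, amplicon: str, scoring: ScoringScheme):
    """Alignment fast path: a read identical to the amplicon needs no DP."""
    if seq == amplicon:
        return len(amplicon) * scoring.match, [], (0, len(amplicon))
    aln = needleman_wunsch(seq, amplicon, scoring)
    events = extract_events(aln, read_id="")
    cols = list(zip(aln.aligned_ref, aln.aligned_read))
    # sequenced span: first/last aligned (non-gap) column, in ref coordinates
    ref_pos = 0
    first = last = None
    for r, q in cols:
        if r != "-" and q != "-":
            if first is None:
                first = ref_pos
            last = ref_pos + 1
        if r != "-":
            ref_pos += 1
    if first is None:
        first, last = 0, 0
    return aln.score, events, (first, last)


def align_experiment(
    record: ExperimentRecord,
    read_pairs: list,
    params: PipelineParams,
) -> list[AlignedRead]:
    """Align assigned read (pairs) to the amplicon of their experiment.

    Reverse mates are reverse-complemented into amplicon orientation before
    alignment so both mates share forward coordinates; paired-end
    disagreements are resolved by the consensus rules of
    :func:`editscan.align.resolve_paired`.  Identical read sequences reuse a
    cached alignment.
    """
    amplicon = record.amplicon
    cache: dict[str, tuple] = {}
    out: list[AlignedRead] = []
    for fwd, rev in read_pairs:
        if fwd.sequence not in cache:
            cache[fwd.sequence] = _align_one(fwd.sequence, amplicon, params.scoring)
        score_f, events_f, span_f = cache[fwd.sequence]
        aligned_f = AlignedRead(
            read_id=fwd.read_id,
            experiment_id=record.id,
            score_fwd=score_f,
            events=[e.with_read(fwd.read_id) for e in events_f],
            span=span_f,
        )
        if rev is None:
            out.append(aligned_f)
            continue
        rc = reverse_complement(rev.sequence)
        if rc not in cache:
            cache[rc] = _align_one(rc, amplicon, params.scoring)
        score_r, events_r, span_r = cache[rc]
        aligned_r = AlignedRead(
            read_id=rev.read_id,
            experiment_id=record.id,
            score_fwd=score_r,
            events=[e.with_read(fwd.read_id) for e in events_r],
            span=span_r,
        )
        consensus = resolve_paired(aligned_f, aligned_r)
        out.append(
            AlignedRead(
                read_id=fwd.read_id,
                experiment_id=record.id,
                score_fwd=score_f,
                score_rev=score_r,
                events=consensus,
                span=(
                    min(span_f[0], span_r[0]),
                    max(span_f[1], span_r[1]),
                ),
            )
        )
    return out


def build_event_table(
    record: ExperimentRecord,
    aligned: list[AlignedRead],
    params: PipelineParams,
) -> tuple[EventTable, dict]:
    """Apply primer-dimer and artifact filters; collect retained events."""
    dimer_ids = {
        r.read_id
        for r in aligned
        if detect_primer_dimer(
            r.events,
            len(record.amplicon),
            len(record.forward_primer),
            len(record.reverse_primer),
            params.dimer_buffer,
        )
    }
    survivors = [r for r in aligned if r.read_id not in dimer_ids]
    artifact_ids = flag_artifact_reads(survivors, params.artifact)
    retained = [r for r in survivors if r.read_id not in artifact_ids]
    table = EventTable(
        experiment_id=record.id,
        events=[ev for r in retained for ev in r.events],
        read_count_total=len(retained),
        reads_flagged={
            "primer_dimer": len(dimer_ids),
            "artifact": len(artifact_ids),
        },
        read_scores={r.read_id: r.score_fwd for r in retained},
    )
    return table, {"primer_dimer": len(dimer_ids), "artifact": len(artifact_ids)}


def run_pipeline(
    config: str | Path | list[ExperimentRecord],
    params: PipelineParams | None = None,
    output_dir: str | Path | None = None,
    base_dir: str | Path | None = None,
) -> dict[str, ExperimentResult]:
    """Run the complete analysis for every experiment in a configuration.

    ``config`` is a configuration CSV path or a pre-loaded record list;
    relative FASTQ paths are resolved against ``base_dir`` (default: the
    configuration file's directory).  When ``output_dir`` is given, writes
    ``events_<id>.tsv``, ``stats.json``, ``aggregates_<level>.tsv`` and
    ``filter_report.tsv``.
    """
    params = params or PipelineParams()
    if isinstance(config, (str, Path)):
        records = load_experiment_config(config)
        base = Path(base_dir) if base_dir else Path(config).parent
    else:
        records = config
        base = Path(base_dir) if base_dir else Path(".")

    # group experiments by their FASTQ file pair (one barcode file-group)
    groups: dict[tuple, list[ExperimentRecord]] = {}
    for rec in records:
        groups.setdefault((rec.fastq_fwd, rec.fastq_rev), []).append(rec)

    results: dict[str, ExperimentResult] = {}
    tallies: list[report_mod.FilterTally] = []
    raw_tables: dict[str, EventTable] = {}
    file_meta: dict[str, dict] = {}

    for (fwd_file, rev_file), members in groups.items():
        fwd_path = base / fwd_file
        rev_path = base / rev_file if rev_file else None
        pairs = read_fastq_pairs(fwd_path, rev_path)
        by_exp, tally, _ = assign_reads(
            pairs,
            members,
            params.quality,
            params.primer_mismatches,
            anchored=params.primer_scan_window == 0,
            scan_window=params.primer_scan_window,
        )
        shared = len(members) > 1
        if shared:
            tallies.append(
                report_mod.FilterTally(
                    id=f"{members[0].barcode or fwd_file}(file)",
                    input_reads=tally.quality_rejected + tally.unassigned,
                    quality_rejected=tally.quality_rejected,
                    unassigned=tally.unassigned,
                )
            )
        for rec in members:
            aligned = align_experiment(rec, by_exp[rec.id], params)
            table, flag_counts = build_event_table(rec, aligned, params)
            raw_tables[rec.id] = table
            file_meta[rec.id] = {
                "shared": shared,
                "quality_rejected": tally.quality_rejected,
                "unassigned": tally.unassigned,
                "assigned": tally.per_experiment[rec.id],
            }

    # normalization: controls are processed identically above, then each
    # treatment is normalized against the union of its controls
    final_tables: dict[str, EventTable] = {}
    for rec in records:
        table = raw_tables[rec.id]
        if rec.is_control:
            final_tables[rec.id] = table
            continue
        ctrl_records = controls_for(rec, records)
        ctrl_tables = [raw_tables[c.id] for c in ctrl_records]
        if ctrl_tables:
            control = merge_event_tables(ctrl_tables, f"{rec.id}__control")
            table = normalize_with_control(
                table,
                control,
                params.control_noise_threshold,
                slack=params.normalization_slack,
            )
        final_tables[rec.id] = table

    for rec in records:
        table = final_tables[rec.id]
        meta = file_meta[rec.id]
        window = locate_cut_window(
            rec.amplicon,
            rec.guide_rna,
            flank=params.cut_flank,
            cut_offset=params.cut_offset,
            override=rec.cut_window_override,
        )
        flags = raw_tables[rec.id].reads_flagged
        tally_row = report_mod.FilterTally(
            id=rec.id,
            input_reads=meta["assigned"],
            primer_dimer=flags["primer_dimer"],
            artifact=flags["artifact"],
            retained=table.read_count_total,
        )
        if not meta["shared"]:
            tally_row.input_reads += meta["quality_rejected"] + meta["unassigned"]
            tally_row.quality_rejected = meta["quality_rejected"]
            tally_row.unassigned = meta["unassigned"]
        tallies.append(tally_row)

        if table.read_count_total == 0:
            stats = EditingStats(filter_tallies=tally_row.__dict__.copy())
        else:
            stats = compute_efficiency(table, window)
            stats.heterogeneity = compute_heterogeneity(table)
            stats.filter_tallies = {
                k: v for k, v in tally_row.__dict__.items() if k != "id"
            }
            if rec.donor:
                expected = hdr_expected_events(
                    rec.donor, rec.amplicon, params.scoring
                )
                hdr_stats = quantify_hdr(table, expected, window)
                stats.reads_hdr = hdr_stats.reads_hdr
                stats.reads_nhej = hdr_stats.reads_nhej
                stats.hdr_pct = hdr_stats.hdr_pct
                stats.nhej_pct = hdr_stats.nhej_pct
        results[rec.id] = ExperimentResult(
            record=rec,
            raw_table=raw_tables[rec.id],
            table=table,
            stats=stats,
            tally=tally_row,
        )

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec in records:
            write_event_table(final_tables[rec.id], out / f"events_{rec.id}.tsv")
        write_stats_json(
            {rid: r.stats for rid, r in results.items()}, out / "stats.json"
        )
        pairs = [(r.record, r.stats) for r in results.values()]
        for level in report_mod.AGGREGATION_LEVELS:
            report_mod.aggregate(pairs, level).to_csv(
                out / f"aggregates_{level}.tsv", sep="\t", index=False
            )
        report_mod.filter_report(tallies).to_csv(
            out / "filter_report.tsv", sep="\t", index=False
        )
    return results
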