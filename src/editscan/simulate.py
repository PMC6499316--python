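"""Ground-truth read simulator for validating the quantification pipeline.

Each simulated locus is a random amplicon whose first and last 20 nt serve
as primers and which carries a unique 20-nt guide site with an NGG PAM near
the center.  Reads are full-length amplicon copies: an edited read carries a
single indel placed at the cut site, an HDR read is a copy of the donor
template, an NHEJ read carries a cut-site indel without the donor events,
and a contaminant (off-target) read is an amplicon copy substituted at a
fixed per-base mismatch rate.  Sequencing errors are uniform substitutions.
Every random draw flows from one seeded generator, so outputs are
byte-identical for a given seed.

The default conditions reproduce the benchmark design used to validate the
method: 20 loci, editing efficiencies drawn from {0%, 33.3%, 66.7%, 90%},
contaminants at a 30% per-base mismatch rate, and indel lengths partitioned
into short (<10 bp) and long (>=10 bp) regimes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .align import reverse_complement
from .config_io import ExperimentRecord, SequencedRead, write_experiment_config, write_fastq

__all__ = [
    "SimulationSpec",
    "SimulatedDataset",
    "simulate_experiment",
    "simulate_dataset",
    "simulate_contaminants",
    "EFFICIENCY_LEVELS",
]

# editing-efficiency levels of the reference benchmark design
EFFICIENCY_LEVELS = (0.0, 1 / 3, 2 / 3, 0.9)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_INDEL_RANGES = {
    "short_only": (1, 9),
    "mixed": (1, 25),
    "long_insertions": (10, 25),
    "long_deletions": (10, 25),
}

_PRIMER_LEN = 20
_GUIDE_LEN = 20
_DEFAULT_QUAL = 37
# edited-read indels start within ±2 nt of the cut so that left-normalization
# through a chance repeat cannot carry them outside the ±5 counting window
_PLACEMENT_JITTER = 2
_HDR_INSERT = "GGATCC"


@dataclass(frozen=True)
class SimulationSpec:
    """Generating conditions of one synthetic benchmark dataset."""

    n_loci: int = 20
    amplicon_length: int = 200
    reads_per_locus: int = 1000
    efficiency: float = 1 / 3
    indel_length_range: tuple[int, int] | None = None
    long_indel_mode: str = "short_only"
    hdr_fraction: float = 0.0
    nhej_fraction: float = 0.0
    contaminant_fraction: float = 0.0
    contaminant_mismatch_rate: float = 0.30
    seq_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in (
            "efficiency",
            "hdr_fraction",
            "nhej_fraction",
            "contaminant_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.hdr_fraction + self.nhej_fraction > 1.0:
            raise ValueError("hdr_fraction + nhej_fraction must be <= 1")
        if self.long_indel_mode not in _INDEL_RANGES:
            raise ValueError(f"unknown long_indel_mode {self.long_indel_mode!r}")
        if self.amplicon_length < 2 * _PRIMER_LEN + _GUIDE_LEN + 40:
            raise ValueError("amplicon_length too short for primers + guide site")

    @property
    def indel_range(self) -> tuple[int, int]:
        return self.indel_length_range or _INDEL_RANGES[self.long_indel_mode]

    @property
    def hdr_mode(self) -> bool:
        return self.hdr_fraction + self.nhej_fraction > 0


@dataclass
class SimulatedDataset:
    """In-memory result of one simulation."""

    records: list[ExperimentRecord]
    reads: dict[str, list[SequencedRead]]  # experiment id -> reads
    truth: pd.DataFrame  # read_id, experiment_id, category, edited, net_indel


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _make_locus(rng: np.random.Generator, spec: SimulationSpec):
    """Random amplicon with a unique guide site (NGG PAM) near the center."""
    L = spec.amplicon_length
    for _ in range(100):
        seq = list(_random_seq(rng, L))
        p = L // 2 - 17  # guide start: cut (p+17) lands mid-amplicon
        seq[p + _GUIDE_LEN + 1] = "G"
        seq[p + _GUIDE_LEN + 2] = "G"
        amplicon = "".join(seq)
        guide = amplicon[p : p + _GUIDE_LEN]
        occ = amplicon.count(guide) + amplicon.count(reverse_complement(guide))
        if occ == 1:
            cut = p + _GUIDE_LEN - 3
            return amplicon, guide, cut
    raise RuntimeError("could not draw an amplicon with a unique guide site")


def _edited_read(
    rng: np.random.Generator, amplicon: str, cut: int, spec: SimulationSpec
) -> tuple[str, int]:
    """Amplicon copy with one cut-site indel; returns (sequence, net indel)."""
    lo, hi = spec.indel_range
    length = int(rng.integers(lo, hi + 1))
    mode = spec.long_indel_mode
    if mode == "long_insertions":
        is_insertion = True
    elif mode == "long_deletions":
        is_insertion = False
    else:
        is_insertion = bool(rng.integers(0, 2))
    pos = cut + int(rng.integers(-_PLACEMENT_JITTER, _PLACEMENT_JITTER + 1))
    if is_insertion:
        ins = _random_seq(rng, length)
        return amplicon[:pos] + ins + amplicon[pos:], length
    end = min(pos + length, len(amplicon) - _PRIMER_LEN)
    return amplicon[:pos] + amplicon[end:], -(end - pos)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base independently with probability ``rate``."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.shape[0]) < rate)[0]
    if hit.size:
        # draw uniformly from the three alternative bases
        cur_idx = np.searchsorted(_BASES, arr[hit])
        shift = rng.integers(1, 4, size=hit.size)
        arr[hit] = _BASES[(cur_idx + shift) % 4]
    return arr.tobytes().decode("ascii")


def simulate_contaminants(
    amplicon: str, rate: float, n: int, seed: int | np.random.Generator = 0
) -> list[str]:
    """Off-target reads: amplicon copies substituted at ``rate`` per base."""
    if not 0 < rate < 1:
        raise ValueError("contaminant mismatch rate must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [_mutate(rng, amplicon, rate) for _ in range(n)]


def simulate_dataset(spec: SimulationSpec) -> SimulatedDataset:
    """Generate a full multi-locus benchmark dataset in memory."""
    rng = np.random.default_rng(spec.seed)
    records: list[ExperimentRecord] = []
    reads: dict[str, list[SequencedRead]] = {}
    truth_rows = []
    for locus in range(spec.n_loci):
        amplicon, guide, cut = _make_locus(rng, spec)
        exp_id = f"L{locus:02d}"
        donor = None
        if spec.hdr_mode:
            donor = amplicon[:cut] + _HDR_INSERT + amplicon[cut:]
        records.append(
            ExperimentRecord(
                id=exp_id,
                barcode=f"bc{locus:02d}",
                forward_primer=amplicon[:_PRIMER_LEN],
                reverse_primer=reverse_complement(amplicon[-_PRIMER_LEN:]),
                guide_rna=guide,
                amplicon=amplicon,
                donor=donor,
                group="sim",
                is_control=False,
                fastq_fwd=f"{exp_id}.fastq.gz",
            )
        )
        locus_reads: list[SequencedRead] = []
        for r in range(spec.reads_per_locus):
            read_id = f"{exp_id}_r{r:05d}"
            u = rng.random()
            net = 0
            if u < spec.contaminant_fraction:
                category = "contaminant"
                seq = _mutate(rng, amplicon, spec.contaminant_mismatch_rate)
            elif spec.hdr_mode:
                v = rng.random()
                if v < spec.hdr_fraction:
                    category = "hdr"
                    seq = donor
                    net = len(_HDR_INSERT)
                elif v < spec.hdr_fraction + spec.nhej_fraction:
                    category = "nhej"
                    seq, net = _edited_read(rng, amplicon, cut, spec)
                else:
                    category = "unedited"
                    seq = amplicon
            elif rng.random() < spec.efficiency:
                category = "edited"
                seq, net = _edited_read(rng, amplicon, cut, spec)
            else:
                category = "unedited"
                seq = amplicon
            if spec.seq_error_rate > 0:
                seq = _mutate(rng, seq, spec.seq_error_rate)
            locus_reads.append(
                SequencedRead(
                    read_id=read_id,
                    sequence=seq,
                    qualities=[_DEFAULT_QUAL] * len(seq),
                    mate="single",
                )
            )
            truth_rows.append(
                {
                    "read_id": read_id,
                    "experiment_id": exp_id,
                    "category": category,
                    "edited": category in ("edited", "hdr", "nhej"),
                    "net_indel": net,
                }
            )
        reads[exp_id] = locus_reads
    truth = pd.DataFrame(truth_rows)
    return SimulatedDataset(records=records, reads=reads, truth=truth)


def simulate_experiment(
    spec: SimulationSpec, output_dir: str | Path
) -> tuple[Path, Path, Path]:
    """Write a simulated dataset to disk.

    Produces ``config.csv``, one gzip FASTQ per locus, ``truth.tsv`` and a
    ``spec.json`` provenance file; returns the three main paths.  Outputs are
    byte-identical for identical specs (including the seed).
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(spec)
    for rec in ds.records:
        write_fastq(ds.reads[rec.id], out / rec.fastq_fwd)
    config_path = out / "config.csv"
    write_experiment_config(ds.records, config_path)
    truth_path = out / "truth.tsv"
    ds.truth.to_csv(truth_path, sep="\t", index=False)
    spec_payload = asdict(spec)
    with open(out / "spec.json", "w") as fh:
        json.dump(spec_payload, fh, indent=2)
        fh.write("\n")
    return config_path, truth_path, out
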