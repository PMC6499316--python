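from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from editscan.config_io import ExperimentRecord, SequencedRead
from editscan.pipeline import PipelineParams, align_experiment, build_event_table
from editscan.simulate import SimulationSpec, simulate_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def locus():
    """One simulated locus: (record, cut coordinate)."""
    ds = simulate_dataset(
        SimulationSpec(n_loci=1, reads_per_locus=1, efficiency=0.0, seed=7)
    )
    rec = ds.records[0]
    from editscan.quantify import locate_cut_window

    window = locate_cut_window(rec.amplicon, rec.guide_rna)
    cut = (window.start + window.end) // 2
    return rec, cut


def table_from_sequences(record: ExperimentRecord, sequences, params=None):
    """Align raw read sequences and build the filtered event table."""
    params = params or PipelineParams()
    reads = [
        (
            SequencedRead(f"r{i:05d}", seq, [37] * len(seq)),
            None,
        )
        for i, seq in enumerate(sequences)
    ]
    aligned = align_experiment(record, reads, params)
    table, _ = build_event_table(record, aligned, params)
    return table
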