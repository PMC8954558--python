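from __future__ import annotations

import numpy as np
import pytest

from srrna_scout.align import align_read, build_index
from srrna_scout.pipeline import build_mapping_table, select_rdna_reads
from srrna_scout.qc import deduplicate, trim_dataset
from srrna_scout.synthetic import StudyConfig, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """The default-scale synthetic study used by the recovery and
    permutation-collapse checks."""
    return simulate_study(StudyConfig(), seed=20260926)


@pytest.fixture(scope="session")
def default_run(default_study):
    """The observed pipeline run on the default study: indexes, mapping
    records and copy counts, shared across end-to-end tests."""
    study = default_study
    trimmed, trim_counts = trim_dataset(study.reads)
    rdna_index = build_index({study.rdna.name: study.rdna.sequence})
    selected, rdna_alignments = select_rdna_reads(trimmed, rdna_index, max_mismatch=2)
    genome_index = build_index(study.genome)
    unique = deduplicate(selected)
    copy_counts = {u.representative.read_id: u.copy_count for u in unique}
    aligned = []
    for u in unique:
        aln = align_read(u.representative, genome_index, max_mismatch=1)
        if aln is not None:
            aligned.append(aln)
    records = build_mapping_table(
        aligned,
        raw_sequences={r.read_id: r.sequence for r in study.reads},
        copy_counts=copy_counts,
    )
    return {
        "study": study,
        "trim_counts": trim_counts,
        "trimmed": trimmed,
        "rdna_index": rdna_index,
        "genome_index": genome_index,
        "selected": selected,
        "rdna_alignments": rdna_alignments,
        "records": records,
        "observed_mapped_reads": sum(r.read_count for r in records),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
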