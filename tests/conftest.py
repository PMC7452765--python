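"""Shared fixtures: the default synthetic dataset and derived filters."""

import io

import pytest

from exograph.baiting import (
    BaitingParams,
    build_baited_solid_filter,
    build_transcriptome_filter,
)
from exograph.simulate import GenomeSpec, ReadSpec, simulate_genome, simulate_reads


@pytest.fixture(scope="session")
def default_data():
    """Default toy dataset: 20 genes, 2-4 exons each, seed 42."""
    return simulate_genome(GenomeSpec())


@pytest.fixture(scope="session")
def tx_fasta(default_data):
    return "".join(
        f">{tid}\n{seq}\n" for tid, seq in default_data.transcripts.items()
    )


@pytest.fixture(scope="session")
def clean_reads(default_data):
    """Error-free single-end reads at 30x coverage."""
    (fq,) = simulate_reads(default_data, ReadSpec(coverage=30, seed=3))
    return fq


@pytest.fixture(scope="session")
def truth_intervals(default_data):
    return [iv for ivs in default_data.truth_bed.values() for iv in ivs]


@pytest.fixture(scope="session")
def exact_solid(tx_fasta, clean_reads):
    """Exact-count solid k-mer set built through the baited pipeline."""
    params = BaitingParams(k=25, levels=2, memory_bits=1 << 22)
    tf = build_transcriptome_filter(io.StringIO(tx_fasta), params)
    solid, summary = build_baited_solid_filter(
        io.StringIO(clean_reads), tf, params, backend="exact"
    )
    assert summary.kept > 0
    return solid
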