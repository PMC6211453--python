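import numpy as np
import pytest

from clippeaks import nhmm, readprep as rp
from clippeaks import simulator as sim


def make_read(
    start=100,
    length=30,
    strand="+",
    mismatches=(),
    deletions=(),
    chrom="chr1",
):
    return rp.AlignedRead(
        chrom=chrom,
        start=start,
        end=start + length + len(deletions),
        strand=strand,
        read_length=length,
        mismatches=list(mismatches),
        deletions=list(deletions),
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated experiment shared across tests (seeded)."""
    cfg = sim.SimConfig(
        n_genes=12,
        gene_length_range=(600, 900),
        reads_per_library=15_000,
        seed=7,
    )
    return sim.simulate_libraries(cfg)


@pytest.fixture(scope="session")
def small_tensors(small_sim):
    reads = [sim.to_aligned_reads(lib, small_sim) for lib in small_sim.libraries]
    roles = [lib.role for lib in small_sim.libraries]
    return rp.build_tensors(reads, small_sim.genes, roles)


@pytest.fixture(scope="session")
def small_fit(small_tensors):
    """One EM fit of the small experiment, reused by decoding-level tests."""
    config = nhmm.FitConfig(seed=19, min_iter=3, max_iter=6)
    return nhmm.em_fit(small_tensors, config)
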