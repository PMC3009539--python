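import numpy as np
import pytest

from pol2prom.genome_io import TagTrack
from pol2prom.simulate import SimulationConfig, make_benchmark


@pytest.fixture(scope="session")
def small_bench():
    """Small but complete synthetic benchmark shared across module tests."""
    cfg = SimulationConfig(seed=7, genome_length=2_400_000, n_genes=90)
    return make_benchmark(cfg)


@pytest.fixture()
def uniform_track():
    """Factory for simple single-chromosome tracks."""

    def make(coverage, library_size=None, chrom="chr1", assay="polII",
             sample_id="t"):
        cov = np.asarray(coverage, dtype=np.int64)
        if library_size is None:
            library_size = max(int(cov.sum()), 1)
        return TagTrack(sample_id=sample_id, assay=assay,
                        coverage={chrom: cov}, library_size=library_size)

    return make
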