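import io

import pytest

from microsketch import SketchConfig, read_fastq, sketch_stream
from microsketch.synthetic_data import generate_reads, make_community


def sketch_from_reads(community, n_reads, read_length, config, seed, error_rate=0.001):
    """Generate reads from a community and sketch them in one pass."""
    fq = generate_reads(community, n_reads, read_length, error_rate, seed=seed)
    return list(sketch_stream(read_fastq(io.BytesIO(fq)), config))[-1]


@pytest.fixture(scope="session")
def small_community():
    return make_community(n_taxa=5, genome_length=500, seed=1)


@pytest.fixture(scope="session")
def small_config():
    return SketchConfig(k=21, sketch_size=64, num_bins=2000, epsilon=1e-5, master_seed=5)
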