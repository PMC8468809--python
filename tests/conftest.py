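import numpy as np
import pytest

from xtalk import simulate


@pytest.fixture(scope="session")
def paper_tables():
    """Classified gene and DMR tables matching the published worked example."""
    return simulate.paper_counts_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def genome_fixture():
    """A 100 kb genome with genes, TEs, CpG-enriched intervals and motifs."""
    motifs = [("chr1", 120, "DR", 4), ("chr1", 160, "IR", 3), ("chr1", 200, "ER", 6)]
    return simulate.simulate_genome(seq_len=100_000, planted_motifs=motifs, seed=7)
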