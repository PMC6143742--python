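import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from streamline_scan import synthetic_data as sd


@pytest.fixture
def small_genome():
    """A deterministic small synthetic genome with QC record and truth."""
    spec = sd.GenomeSimSpec(n_contigs=3, genes_per_contig=8, seed=42)
    return sd.simulate_genome(spec, genome_id="GFIX")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
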