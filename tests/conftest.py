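import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from xenosig import simulate as sim


@pytest.fixture(scope="session")
def host_model():
    return sim.make_codon_model(0.55, seed=11)


@pytest.fixture(scope="session")
def donor_model():
    return sim.make_codon_model(0.70, seed=12)


@pytest.fixture(scope="session")
def small_genome(host_model):
    """120 native genes from one codon model (no transfers)."""
    genes, _ = sim.generate_genome_with_transfers(120, host_model, seed=7)
    return genes
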