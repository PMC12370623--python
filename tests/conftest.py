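import pytest

from dualguide import synth_genome


@pytest.fixture(scope="session")
def small_truth():
    """12-gene genome with operons; every window carries a planted site."""
    return synth_genome(n_genes=12, operon_fraction=0.4, seed=11)


@pytest.fixture(scope="session")
def sparse_truth():
    """30-gene genome where some windows are deliberately PAM-free."""
    return synth_genome(n_genes=30, operon_fraction=0.3, seed=37, plant_prob=0.85)
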