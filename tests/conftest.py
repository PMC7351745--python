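import pytest

from triad.genemodel import TargetGene, generate_synthetic_target


@pytest.fixture(scope="session")
def gene999():
    """Standard ~1 kb synthetic target used across tests."""
    return generate_synthetic_target(999, gc=0.5, seed=1)


@pytest.fixture(scope="session")
def toy60():
    """60-bp toy gene for exhaustive brute-force comparisons."""
    return generate_synthetic_target(60, gc=0.5, seed=7)


@pytest.fixture(scope="session")
def toy_codon_gene():
    """Tiny hand-readable gene: ATG AAA CCC GGG TAA."""
    return TargetGene("toy", "ATGAAACCCGGGTAA", 0, 15)
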