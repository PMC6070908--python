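import pytest

import phagepipe as pp


@pytest.fixture(scope="session")
def default_genome():
    """A Table-2-scale genome: ~40 kbp, 66 genes (the Pagassa regime)."""
    return pp.make_genome(pp.GenomeSpec(length_bp=40000, n_genes=66, seed=1))


@pytest.fixture(scope="session")
def small_genome():
    return pp.make_genome(pp.GenomeSpec(length_bp=5000, n_genes=8, seed=3))


@pytest.fixture(scope="session")
def strong_evidence(default_genome):
    _, truth = default_genome
    return pp.EvidenceBundle.from_table(pp.make_evidence(truth, "strong", seed=5))
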