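import pytest

import srnakit as sk


@pytest.fixture(scope="session")
def small_bundle():
    """A 40-gene toy genome shared across tests."""
    return sk.generate_genome(40, gene_length_range=(500, 1200), seed=7)


@pytest.fixture(scope="session")
def small_index(small_bundle):
    return sk.ExactMatchIndex.from_bundle(small_bundle)
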