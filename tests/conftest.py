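import random

import pytest

from jellyseq.synthio import GenomeConfig, make_genome


@pytest.fixture(scope="session")
def small_genome():
    """A compact genome with planted intergenic hairpins, shared across tests."""
    return make_genome(GenomeConfig(length=8_000, n_genes=3, gene_length=900,
                                    exons_per_gene=3, intron_length=120,
                                    n_rrna=1, rrna_length=300, n_hairpins=2),
                       seed=101)


@pytest.fixture()
def rng():
    return random.Random(20240917)
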