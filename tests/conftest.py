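import numpy as np
import pytest

import stratdeg as sd


@pytest.fixture(scope="session")
def table1_matrix():
    """The canonical two-gene, two-tissue Simpson-reversal demonstration."""
    return sd.table1_count_matrix()


@pytest.fixture(scope="session")
def table1_table(table1_matrix):
    return sd.build_gene_table(table1_matrix, "GENE_A")


@pytest.fixture(scope="session")
def small_corpus():
    """A compact synthetic clone-library corpus with 25% contamination."""
    return sd.generate_library_corpus(
        n_libraries=24, contamination=0.25, n_genes=12,
        mean_library_ests=500, seed=11,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
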