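import numpy as np
import pandas as pd
import pytest

from rhizoecol import CommunityTable, simulate_phylogeny


@pytest.fixture(scope="session")
def tree8():
    return simulate_phylogeny(8, seed=7)


@pytest.fixture(scope="session")
def tree30():
    return simulate_phylogeny(30, seed=2)


def make_sparse_table(n_samples=8, n_taxa=30, seed=0, conc=0.3, depth=300):
    """Random sparse count table (Dirichlet-multinomial) with membership turnover."""
    rng = np.random.default_rng(seed)
    base = rng.dirichlet(np.full(n_taxa, conc))
    counts = np.vstack(
        [rng.multinomial(depth, rng.dirichlet(base * 50)) for _ in range(n_samples)]
    )
    return CommunityTable(
        pd.DataFrame(
            counts,
            index=[f"S{i}" for i in range(n_samples)],
            columns=[f"T{i}" for i in range(n_taxa)],
        )
    )


@pytest.fixture()
def sparse_table():
    return make_sparse_table()
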