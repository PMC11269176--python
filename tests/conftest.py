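import numpy as np
import pandas as pd
import pytest

import aerospora as ap
from aerospora import quantify

SMALL_CFG = ap.SimConfig(
    seed=1,
    n_sites=8,
    ranks_fanout=(2, 2, 2, 1, 2, 3),  # 48 species
    date_range=("2021-01-01", "2022-06-30"),
)


@pytest.fixture(scope="session")
def small_cfg():
    return SMALL_CFG


@pytest.fixture(scope="session")
def small_ds():
    """48 species x 8 sites x 78 weekly dates; the workhorse fixture."""
    return ap.generate(SMALL_CFG)


@pytest.fixture(scope="session")
def small_filtered(small_ds):
    return quantify.filter_by_depth(small_ds.otu_table)


@pytest.fixture(scope="session")
def small_presence(small_filtered):
    fungal, _ = quantify.split_spike(small_filtered)
    return fungal > 0


@pytest.fixture(scope="session")
def small_quant(small_filtered):
    return quantify.compute_dna_amount(small_filtered)


@pytest.fixture(scope="session")
def toy_taxonomy():
    """Hand-built two-kingdom taxonomy with known pairwise relations."""
    rows = [
        # otu, kingdom, phylum, class, order, family, genus, species
        ("A", "K1", "P1", "C1", "O1", "F1", "G1", "s_A"),
        ("B", "K1", "P1", "C1", "O1", "F1", "G1", "s_B"),  # congeneric with A
        ("C", "K1", "P1", "C1", "O1", "F1", "G2", "s_C"),  # confamilial with A
        ("D", "K1", "P1", "C1", "O2", "F2", "G3", "s_D"),  # same class as A
        ("E", "K1", "P2", "C2", "O3", "F3", "G4", "s_E"),  # same kingdom only
        ("F", "K2", "P3", "C3", "O4", "F4", "G5", "s_F"),  # different kingdom
    ]
    return pd.DataFrame(
        rows,
        columns=["otu_id", "kingdom", "phylum", "class", "order", "family", "genus", "species"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
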