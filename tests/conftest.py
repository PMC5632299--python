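"""Shared fixtures: small trees, equal codon frequencies, tiny alignments."""

from pathlib import Path

import numpy as np
import pytest

import flightsel as fs

DATA_DIR = Path(__file__).resolve().parent.parent / "data"


@pytest.fixture(scope="session")
def code():
    return fs.get_code()


@pytest.fixture(scope="session")
def equal_freqs(code):
    return np.full(code.n_states, 1.0 / code.n_states)


@pytest.fixture
def three_taxon_tree():
    return fs.LabeledTree.from_newick("((A:0.1,B:0.2):0.15,C:0.3);")


@pytest.fixture
def panel_tree():
    """8-taxon tree with one focal (class 1) internal branch."""
    return fs.LabeledTree.from_newick(
        "((((a1:0.08,a2:0.08)#1:0.15,(b1:0.06,b2:0.09):0.07):0.05,"
        "(c1:0.1,c2:0.12):0.06):0.04,(d1:0.11,d2:0.07):0.09);"
    )


@pytest.fixture
def rates_tree():
    """8-taxon tree with flightless (1) and flying (2) clades over background."""
    return fs.LabeledTree.from_newick(
        "(((a1:0.1,a2:0.1)#1:0.08,(b1:0.1,b2:0.1)#2:0.08):0.05,"
        "((c1:0.1,c2:0.1):0.05,(d1:0.1,d2:0.1):0.05):0.05);"
    )


@pytest.fixture
def rates_tree_full():
    """Rates tree with the whole focal clades (stem + members) labeled."""
    return fs.LabeledTree.from_newick(
        "(((a1#1:0.1,a2#1:0.1)#1:0.08,(b1#2:0.1,b2#2:0.1)#2:0.08):0.05,"
        "((c1:0.1,c2:0.1):0.05,(d1:0.1,d2:0.1):0.05):0.05);"
    )


@pytest.fixture(scope="session")
def reference_counts():
    import pandas as pd

    return pd.read_csv(DATA_DIR / "enrichment_reference_counts.tsv", sep="\t", comment="#")


@pytest.fixture(scope="session")
def grouped_counts():
    import pandas as pd

    return pd.read_csv(DATA_DIR / "grouped_fisher_counts.tsv", sep="\t", comment="#")
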