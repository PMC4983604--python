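import numpy as np
import pytest

import richrates as rr


@pytest.fixture(scope="session")
def three_tip_tree() -> rr.Phylogeny:
    """((A:1,B:1):1,C:2); — root depth 2, one internal node at depth 1."""
    return rr.read_tree("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def star4_tree() -> rr.Phylogeny:
    """Four tips, no shared history, all branches of length 2."""
    return rr.read_tree("(A:2,B:2,C:2,D:2);")


@pytest.fixture(scope="session")
def clade_table() -> rr.CladeTable:
    return rr.CladeTable(rr.datasets.load_plethodontid_clades(), provenance="packaged")


@pytest.fixture(scope="session")
def backbone_tree() -> rr.Phylogeny:
    return rr.datasets.load_backbone_tree()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20160726)
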