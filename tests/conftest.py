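import numpy as np
import pytest

from karyoevo.karyodata import KaryotypeRecord, Phylogeny


@pytest.fixture
def rng():
    return np.random.default_rng(20260903)


@pytest.fixture
def three_tip_tree():
    return Phylogeny.from_newick("(A:1,(B:0.5,C:0.5):0.5);")


@pytest.fixture
def four_tip_tree():
    return Phylogeny.from_newick("((A:0.4,B:0.4):0.6,(C:0.7,D:0.7):0.3);")


@pytest.fixture
def simple_records():
    return [
        KaryotypeRecord("A", 9, "XY"),
        KaryotypeRecord("B", 9, "XY"),
        KaryotypeRecord("C", 10, "neoXY"),
    ]


def write_csv(path, text):
    path.write_text(text)
    return path
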