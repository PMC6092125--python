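import numpy as np
import pytest

from coaltrait import SpeciesTree, five_taxon_tree, three_taxon_tree


@pytest.fixture
def tree3() -> SpeciesTree:
    return three_taxon_tree()


@pytest.fixture
def tree5() -> SpeciesTree:
    return five_taxon_tree()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
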