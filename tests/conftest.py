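import numpy as np
import pytest

from pmhc.structio.model import AtomSelection
from pmhc.synth import make_chain, make_complex


@pytest.fixture
def complex_model():
    return make_complex()


@pytest.fixture
def peptide_chain():
    return make_chain("C", 10, start_res=55)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def peptide_backbone_sel():
    return AtomSelection(chain="C", atom_class="backbone-no-O")


@pytest.fixture
def peptide_heavy_sel():
    return AtomSelection(chain="C", atom_class="all-heavy")


@pytest.fixture
def receptor_backbone_sel():
    return AtomSelection(chain="A", atom_class="backbone-no-O")
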