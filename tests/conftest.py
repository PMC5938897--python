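import numpy as np
import pytest

from updown.glyphs import generate_glyphs, train_ensemble
from updown.kappa import load_bundled
from updown.ladder import Assay, build_ladder
from updown.layout import build_layout
from updown.repair import Lexicon
from updown.staircase import enumerate_valid_tables

ALL_ASSAYS = list(Assay)


@pytest.fixture(scope="session")
def kappa_table():
    return load_bundled()


@pytest.fixture(scope="session")
def mouse_ladder():
    return build_ladder(Assay.MOUSE)


@pytest.fixture(scope="session")
def lexicons():
    return {a: enumerate_valid_tables(build_ladder(a)) for a in ALL_ASSAYS}


@pytest.fixture(scope="session")
def mouse_lexicon():
    return Lexicon.build(Assay.MOUSE)


@pytest.fixture(scope="session")
def ensemble():
    return train_ensemble(generate_glyphs(150, seed=1405))


@pytest.fixture(scope="session")
def mouse_layout():
    return build_layout("mouse")


class ScriptedRng:
    """Stand-in RNG replaying a fixed outcome script: 0.0 forces a
    positive response, a value near 1 forces a negative one."""

    def __init__(self, outcomes):
        self._values = [0.0 if o else 0.999999 for o in outcomes]
        self._i = 0

    def random(self):
        v = self._values[self._i]
        self._i += 1
        return v


@pytest.fixture
def scripted_rng():
    return ScriptedRng
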