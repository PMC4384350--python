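import numpy as np
import pytest

from ibpenum import fixtures as fx
from ibpenum.instance import CAlphaTemplate, CovalentGeometry


@pytest.fixture(scope="session")
def geom():
    return CovalentGeometry()


@pytest.fixture(scope="session")
def template(geom):
    return CAlphaTemplate.from_geometry(geom)


@pytest.fixture(scope="session")
def helix8(geom):
    """An 8-residue ideal poly-alanine helix with full backbone."""
    spec = fx.FixtureSpec(n_residues=8)
    return spec, fx.build_ideal_helix(spec, geom)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)
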