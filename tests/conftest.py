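import numpy as np
import pytest

from nanopep.nanostructures import (build_armchair_nanotube, build_c60,
                                    build_graphene)
from nanopep.synthetic_data import build_peptide_model


@pytest.fixture(scope="session")
def c60():
    return build_c60()


@pytest.fixture(scope="session")
def nanotube():
    return build_armchair_nanotube(n=5, min_length=38.0, cc_bond_length=1.42)


@pytest.fixture(scope="session")
def graphene():
    # compact periodic sheet keeps the classifier tests quick
    return build_graphene(min_x=35.0, min_y=35.0, cc_bond_length=1.42)


@pytest.fixture(scope="session")
def peptide():
    return build_peptide_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
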