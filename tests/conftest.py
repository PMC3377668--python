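import numpy as np
import pytest

from xlscreen.digestion import Peptide, digest
from xlscreen.synthetic_constructs import SYNTHETIC_SHSP_CONSTRUCT
from xlscreen.theory import enumerate_candidates


def make_peptide(seq, start=1, nterm=False, protein_id="p", missed=0):
    """Free-standing peptide with coordinates, for mass-level tests."""
    return Peptide(protein_id, start, start + len(seq) - 1, seq, missed,
                   frozenset(), nterm)


@pytest.fixture(scope="session")
def shsp():
    return SYNTHETIC_SHSP_CONSTRUCT


@pytest.fixture(scope="session")
def shsp_peptides(shsp):
    return digest(shsp, 3)


@pytest.fixture(scope="session")
def shsp_candidates(shsp):
    return enumerate_candidates([shsp])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
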