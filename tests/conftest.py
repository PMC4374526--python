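import numpy as np
import pytest

from genoscreen.align import ScoringScheme
from genoscreen.effects import CdsModel
from genoscreen.synthetic import table_fixture_cds


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme.blosum62()


@pytest.fixture(scope="session")
def tiny_cds() -> CdsModel:
    # ATG AAA CCC GGG TAA -> peptide MKPG
    return CdsModel("ATGAAACCCGGGTAA", upstream_seq="TTTTTTTTTT")


@pytest.fixture(scope="session")
def long_cds() -> CdsModel:
    """7146-nt fixture with AAA at codon 339 and AAG at codon 1371."""
    return table_fixture_cds()


def random_protein(rng: np.random.Generator, length: int, alphabet: str = "ACDEFGHIKLMNPQRSTVWY") -> str:
    return "".join(rng.choice(list(alphabet), size=length))
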