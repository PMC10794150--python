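"""Shared fixtures: a compact 3-position NNK design and small simulations."""

from pathlib import Path

import pytest

from trnadisplay import make_library_design, random_orf

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def design():
    """Compact NNK library: 3 positions on a 40-codon seeded random ORF."""
    return make_library_design(random_orf(40, seed=11), [10, 13, 25], ["NNK"] * 3)


@pytest.fixture(scope="session")
def tiny_design():
    """Two adjacent library positions on a short ORF; amplicon ~ 60 nt."""
    return make_library_design(random_orf(20, seed=5), [6, 9], ["NNK", "NNK"])


@pytest.fixture
def data_dir():
    return DATA_DIR
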