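import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracle.py importable

from peptimine.rules import builtin_protease
from peptimine.synth import gen_panel


@pytest.fixture(scope="session")
def papain():
    return builtin_protease("papain")


@pytest.fixture(scope="session")
def ficin():
    return builtin_protease("ficin")


@pytest.fixture(scope="session")
def bromelain():
    return builtin_protease("bromelain")


@pytest.fixture(scope="session")
def small_panel():
    """A fast panel for unit tests: 4 proteins x 3 enzymes, 24 motifs."""
    return gen_panel(7, n_proteins=4, n_motifs=24, vocab_size=6, n_decoys=10)


@pytest.fixture(scope="session")
def default_panel():
    """The full default panel: 16 proteins x 3 enzymes, 150 planted motifs."""
    return gen_panel(11)
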