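import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from n4 import synthio


@pytest.fixture(scope="session")
def default_config():
    return synthio.SynthConfig(seed=1)


@pytest.fixture(scope="session")
def expression_fixture(default_config):
    """(expr, traits, ledger) for the default planted-module config."""
    return synthio.make_expression(default_config)


@pytest.fixture(scope="session")
def sequence_fixture(default_config):
    """(sequences, gene_models, ledger) with planted G4 motifs."""
    return synthio.make_sequences(default_config)
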