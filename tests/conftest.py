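import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from xenopept import DigestParams, ProteinRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20140527)


@pytest.fixture
def loose_params():
    """Digest params that keep every peptide, exposing the cleavage rule."""
    return DigestParams(max_missed_cleavages=1, min_length=1, max_length=10_000)


@pytest.fixture
def toy_graft():
    """Tiny graft-species proteome used across modules."""
    return [
        ProteinRecord("G1", "toy", "MAKLIRPEPTIDEK"),
        ProteinRecord("G2", "toy", "MVKAAAKLIPKWWR"),
    ]


@pytest.fixture
def toy_host():
    """Host orthologs of toy_graft: differ from it by I<->L swaps only."""
    return [
        ProteinRecord("H1", "toy", "MAKILRPEPTLDEK"),
        ProteinRecord("H2", "toy", "MVKAAAKILPKWWR"),
    ]
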