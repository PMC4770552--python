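import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper module

from nirktools.reference_mapping import Scoring
from nirktools.synthetic_data import SequenceGenConfig, generate_nirk_set, surrogate_reference


@pytest.fixture(scope="session")
def reference():
    return surrogate_reference()


@pytest.fixture(scope="session")
def scoring():
    return Scoring()


@pytest.fixture(scope="session")
def clean_set():
    """Default zero-noise generated set: 10 Clade I + 10 Clade II, seed 1."""
    records, truth, ref = generate_nirk_set(SequenceGenConfig(seed=1))
    return records, truth, ref
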