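from pathlib import Path

import numpy as np
import pytest

from gafd.seqsignal import DNASequence

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140954)


@pytest.fixture
def acgt() -> DNASequence:
    return DNASequence("acgt", "ACGT")
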