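import numpy as np
import pytest

from seqchoice import ChoiceSequence, parse_sequence

#: The ten-trial worked example: five As, five Ss, yet 65% predictable.
WORKED = "SAAASASASS"


@pytest.fixture
def worked_sequence() -> ChoiceSequence:
    return parse_sequence(WORKED)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_sequence(rng: np.random.Generator, n: int) -> ChoiceSequence:
    """A uniform random A/S sequence of length n (test helper)."""
    return ChoiceSequence.from_codes((rng.random(n) < 0.5).astype(int))
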