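import numpy as np
import pytest

from noisefloor import GenomeSequence, TSSSet


@pytest.fixture
def worked_tss() -> TSSSet:
    """The hand-worked TSS example: positions 100/110/140/200, one read each."""
    return TSSSet("chrS", np.array([100, 110, 140, 200]), np.ones(4, dtype=int))


@pytest.fixture
def masked_seq() -> GenomeSequence:
    return GenomeSequence("s", "ACGtttGA")


def random_case_mixed(rng: np.random.Generator, length: int) -> str:
    """A random sequence over {A,C,G,T,N} with random per-character case."""
    chars = rng.choice(list("ACGTN"), size=length)
    lower = rng.random(length) < 0.5
    return "".join(c.lower() if lo else c for c, lo in zip(chars, lower))
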