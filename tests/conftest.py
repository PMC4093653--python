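import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from beante.sequences import GenomeSeq  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(20140711)


def random_dna(rng, n: int, gc: float = 0.4) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))


@pytest.fixture
def random_genome(rng):
    """Element-free 10-kb random sequence."""
    return GenomeSeq("rand", random_dna(rng, 10_000))


def plant_ltr_element(
    background: str, insert_at: int, ltr: str, internal: str, tsd: str
) -> tuple[str, dict]:
    """Manually splice TSD + LTR + internal + LTR + TSD into a background.

    Returns (sequence, layout) where layout records the element span and
    LTR spans in final coordinates.
    """
    element = ltr + internal + ltr
    seq = (background[:insert_at] + tsd + element + tsd
           + background[insert_at:])
    start = insert_at + len(tsd)
    end = start + len(element)
    layout = dict(
        span=(start, end),
        left_ltr=(start, start + len(ltr)),
        right_ltr=(end - len(ltr), end),
        tsd=tsd,
    )
    return seq, layout
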