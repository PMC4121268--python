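import random

import pytest
from hypothesis import settings

from ribocell.model import Amplicon, SampleSet

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def mutate(rng: random.Random, seq: str, n_diffs: int) -> str:
    """Substitute exactly n_diffs distinct positions."""
    positions = rng.sample(range(len(seq)), n_diffs)
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def make_set(entries, sample="cell", replicate="", region="V9") -> SampleSet:
    """SampleSet from (seq, abundance) pairs with generated ids."""
    return SampleSet(
        [
            Amplicon(f"a{i}", seq, ab, sample, replicate, region)
            for i, (seq, ab) in enumerate(entries)
        ]
    )


@pytest.fixture
def rng():
    return random.Random(42)
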