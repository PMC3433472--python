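import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from selexkit.seqio import SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20120904)


def make_record(seq_id: int, variable: str, counts: dict[int, int], **kw) -> SequenceRecord:
    return SequenceRecord(
        id=seq_id, variable_region_dna=variable, reads_per_round=counts, **kw)


@pytest.fixture
def small_database():
    """Six-record database over rounds 0..4 with known counts."""
    return [
        make_record(1, "ACGTACGTACGTACGTACGT", {1: 50, 2: 200, 3: 400, 4: 800}),
        make_record(2, "ACGTACGTACGTACGTACGA", {1: 20, 2: 60, 3: 150, 4: 300}),
        make_record(3, "TTTTCCCCGGGGAAAATTTT", {1: 30, 2: 25, 3: 20, 4: 10}),
        make_record(4, "GACTGACTGACTGACTGACT", {0: 2, 1: 1}),
        make_record(5, "CCCCCCCCCCCCCCCCCCCC", {0: 30}),
        make_record(6, "AGAGAGAGAGAGAGAGAGAG", {2: 3, 4: 4}),
    ]


def random_rna(rng, length: int) -> str:
    return "".join("ACGU"[i] for i in rng.integers(0, 4, size=length))


def random_dna(rng, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def random_dot_bracket(rng, max_len: int = 6) -> str:
    """Random balanced dot-bracket of total length <= max_len."""
    n = int(rng.integers(0, max_len + 1))
    out = []
    depth = 0
    for pos in range(n):
        remaining = n - pos
        if depth == remaining:
            choices = [")"]
        else:
            choices = ["."]
            if depth + 1 <= remaining - 1:
                choices.append("(")
            if depth > 0:
                choices.append(")")
        ch = choices[int(rng.integers(0, len(choices)))]
        out.append(ch)
        depth += {"(": 1, ")": -1, ".": 0}[ch]
    return "".join(out)
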