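import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from famsubmat import (
    AlignmentBlock,
    MultiBlockAlignment,
    SegmentDefinition,
    SequenceRecord,
    SubstitutionMatrix,
)


@pytest.fixture
def toy_block() -> AlignmentBlock:
    """3 sequences x 2 columns: columns [A,A,C] and [L,L,L]."""
    seg = SegmentDefinition("TM1", 0, 2)
    return AlignmentBlock(seg, (("s1", "AL"), ("s2", "AL"), ("s3", "CL")))


@pytest.fixture
def toy_alignment(toy_block) -> MultiBlockAlignment:
    return MultiBlockAlignment(
        records=[SequenceRecord(rid, row) for rid, row in toy_block.rows],
        segments=[toy_block.segment],
    )


@pytest.fixture
def diag_matrix() -> SubstitutionMatrix:
    """S_aa = 4 on the diagonal, 0 elsewhere."""
    scores = np.zeros((20, 20))
    np.fill_diagonal(scores, 4.0)
    return SubstitutionMatrix.from_int_scores(scores)


def random_blocks(rng: np.random.Generator, n: int, max_rows=6, max_cols=5,
                  gap_prob=0.1, ambig_prob=0.05):
    """Random small blocks (as plain row strings) for oracle comparisons."""
    from famsubmat.alphabet import AA_ORDER

    letters = list(AA_ORDER)
    extras = list("X-")
    out = []
    for _ in range(n):
        rows = rng.integers(2, max_rows + 1)
        cols = rng.integers(1, max_cols + 1)
        block = []
        for _r in range(rows):
            chars = []
            for _c in range(cols):
                u = rng.random()
                if u < gap_prob:
                    chars.append("-")
                elif u < gap_prob + ambig_prob:
                    chars.append("X")
                else:
                    chars.append(letters[rng.integers(20)])
            block.append("".join(chars))
        out.append(block)
    return out


def to_alignment_blocks(raw_blocks):
    """Wrap raw row-string blocks into AlignmentBlock objects."""
    blocks = []
    for bi, rows in enumerate(raw_blocks):
        seg = SegmentDefinition(f"B{bi + 1}", 0, len(rows[0]))
        blocks.append(
            AlignmentBlock(seg, tuple((f"r{i}", r) for i, r in enumerate(rows)))
        )
    return blocks
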