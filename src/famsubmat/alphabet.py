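"""Amino-acid alphabet shared by all modules.

The canonical residue order is the NCBI scoring-matrix order
(ARNDCQEGHILKMFPSTWYV), so matrices written by this package line up with
published matrix files.  Ambiguity letters are legal in input sequences but
carry no statistical weight: they are excluded from pair counts, composition
and conservation denominators.
"""

from __future__ import annotations

import numpy as np

#: Canonical residue order used for every 20-vector / 20x20 table.
AA_ORDER: str = "ARNDCQEGHILKMFPSTWYV"

#: Letter -> index in :data:`AA_ORDER`.
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA_ORDER)}

GAP: str = "-"

#: Ambiguity / non-standard letters accepted in input.
AMBIGUOUS: frozenset[str] = frozenset("XBZUO")

#: Every character legal in an aligned sequence.
ALLOWED: frozenset[str] = frozenset(AA_ORDER) | AMBIGUOUS | {GAP}

# Integer codes for fast vectorised work: 0..19 standard residues,
# 20..24 ambiguity letters, -1 gap.
_CODE = {aa: i for i, aa in enumerate(AA_ORDER)}
for _k, _a in enumerate(sorted(AMBIGUOUS)):
    _CODE[_a] = 20 + _k
_CODE[GAP] = -1

_LUT = np.full(128, -2, dtype=np.int8)
for _c, _i in _CODE.items():
    _LUT[ord(_c)] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a residue string to int8 codes (0-19 standard, >=20 ambiguous, -1 gap)."""
    arr = _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == -2).any():
        pos = int(np.argmax(arr == -2))
        raise ValueError(f"illegal character {seq[pos]!r} at position {pos}")
    return arr


def is_standard(code: np.ndarray) -> np.ndarray:
    """Boolean mask of codes that are one of the 20 standard residues."""
    return (code >= 0) & (code < 20)
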