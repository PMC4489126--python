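"""Affine-gap pairwise protein alignment under an arbitrary scoring matrix.

Global alignment is Needleman-Wunsch-Gotoh, local is Smith-Waterman-Gotoh.
Gap costs follow the BLAST "existence/extension" convention: a gap run of
length L costs open + extend * (L - 1), matching how the gap parameters of
database-search tools are stated (the alternative open + extend * L
convention is available via ``gap_convention="open_plus_extend"``).

Traceback is deterministic: ties prefer the diagonal move, then a gap in
the second sequence (consuming the first), then a gap in the first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import SegmentDefinition
from .matrix import SubstitutionMatrix

__all__ = [
    "GapModel",
    "PairwiseAlignment",
    "align",
    "score_alignment",
    "segment_overlap",
]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class GapModel:
    """Affine gap penalties (positive numbers; they are subtracted).

    ``blast`` convention (default): gap of length L costs
    open_penalty + extend_penalty * (L - 1).
    ``open_plus_extend``: costs open_penalty + extend_penalty * L.
    """

    open_penalty: float = 15.0
    extend_penalty: float = 2.0
    convention: str = "blast"

    def __post_init__(self) -> None:
        if not (self.open_penalty >= self.extend_penalty >= 0):
            raise ValueError(
                f"need open_penalty >= extend_penalty >= 0, got "
                f"{self.open_penalty}, {self.extend_penalty}"
            )
        if self.convention not in ("blast", "open_plus_extend"):
            raise ValueError(f"unknown gap convention {self.convention!r}")

    @property
    def first(self) -> float:
        """Cost of the first residue of a gap run."""
        if self.convention == "blast":
            return self.open_penalty
        return self.open_penalty + self.extend_penalty

    @property
    def rest(self) -> float:
        """Cost of each subsequent gap residue."""
        return self.extend_penalty

    def gap_cost(self, length: int) -> float:
        return 0.0 if length == 0 else self.first + self.rest * (length - 1)


@dataclass
class PairwiseAlignment:
    """An aligned pair with its score under the matrix and gap model."""

    aligned_a: str
    aligned_b: str
    score: float
    mode: str
    # local mode: start offsets of the aligned substrings in the inputs
    start_a: int = 0
    start_b: int = 0

    @property
    def identity(self) -> float:
        """Fraction identical over columns with residues in both rows."""
        pairs = [
            (x, y)
            for x, y in zip(self.aligned_a, self.aligned_b)
            if x != "-" and y != "-"
        ]
        if not pairs:
            return 0.0
        return sum(x == y for x, y in pairs) / len(pairs)


def _score_table(m: SubstitutionMatrix, integer: bool) -> tuple[dict[str, int], np.ndarray, float]:
    idx = {aa: i for i, aa in enumerate(m.alphabet)}
    table = (m.scores_int if integer else m.scores_real).astype(float)
    floor = float(table.min())
    return idx, table, floor


def _pair_score(a: str, b: str, idx, table, floor) -> float:
    ia, ib = idx.get(a), idx.get(b)
    if ia is None or ib is None:
        if a == "-" or b == "-":
            raise ValueError("gap character is not a residue")
        return floor  # ambiguity letters score the matrix floor
    return float(table[ia, ib])


def align(
    a: str,
    b: str,
    m: SubstitutionMatrix,
    g: GapModel | None = None,
    mode: str = "global",
    integer: bool = True,
) -> PairwiseAlignment:
    """Optimal pairwise alignment of ``a`` and ``b``.

    Parameters
    ----------
    mode : ``"global"`` (Needleman-Wunsch-Gotoh) or ``"local"``
        (Smith-Waterman-Gotoh).
    integer : score with the rounded integer matrix (default, matching how
        published matrices are consumed) or the real-valued one.

    Returns a :class:`PairwiseAlignment`; removing gaps from the aligned
    strings recovers the inputs (global) or substrings of them (local).
    """
    if g is None:
        g = GapModel()
    if mode not in ("global", "local"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    a, b = a.upper(), b.upper()
    if "-" in a or "-" in b:
        raise ValueError("input sequences must be ungapped")
    idx, table, floor = _score_table(m, integer)
    sub = np.empty((len(a), len(b)))
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            sub[i, j] = _pair_score(x, y, idx, table, floor)
    if mode == "global":
        return _align_global(a, b, sub, g)
    return _align_local(a, b, sub, g)


def _align_global(a: str, b: str, sub: np.ndarray, g: GapModel) -> PairwiseAlignment:
    la, lb = len(a), len(b)
    first, rest = g.first, g.rest
    # state matrices: M diagonal, X gap-in-b (consumes a), Y gap-in-a
    M = np.full((la + 1, lb + 1), NEG_INF)
    X = np.full((la + 1, lb + 1), NEG_INF)
    Y = np.full((la + 1, lb + 1), NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -g.gap_cost(i)
    for j in range(1, lb + 1):
        Y[0, j] = -g.gap_cost(j)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = sub[i - 1, j - 1]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(
                M[i - 1, j] - first, X[i - 1, j] - rest, Y[i - 1, j] - first
            )
            Y[i, j] = max(
                M[i, j - 1] - first, Y[i, j - 1] - rest, X[i, j - 1] - first
            )
    # terminal state: tie order M (diagonal-ending), X, Y
    end_scores = (M[la, lb], X[la, lb], Y[la, lb])
    score = max(end_scores)
    state = ("M", "X", "Y")[end_scores.index(score)]
    out_a, out_b = [], []
    i, j = la, lb
    tol = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = M[i, j] - sub[i - 1, j - 1]
            i, j = i - 1, j - 1
            for prev, val in (("M", M[i, j]), ("X", X[i, j]), ("Y", Y[i, j])):
                if abs(val - target) <= tol:
                    state = prev
                    break
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append("-")
            here = X[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            for prev, val in (
                ("M", M[i, j] - first),
                ("X", X[i, j] - rest),
                ("Y", Y[i, j] - first),
            ):
                if abs(val - here) <= tol:
                    state = prev
                    break
        else:  # Y
            out_a.append("-")
            out_b.append(b[j - 1])
            here = Y[i, j]
            j -= 1
            if i == 0 and j == 0:
                break
            for prev, val in (
                ("M", M[i, j] - first),
                ("Y", Y[i, j] - rest),
                ("X", X[i, j] - first),
            ):
                if abs(val - here) <= tol:
                    state = prev
                    break
    return PairwiseAlignment(
        aligned_a="".join(reversed(out_a)),
        aligned_b="".join(reversed(out_b)),
        score=float(score),
        mode="global",
    )


def _align_local(a: str, b: str, sub: np.ndarray, g: GapModel) -> PairwiseAlignment:
    la, lb = len(a), len(b)
    first, rest = g.first, g.rest
    M = np.zeros((la + 1, lb + 1))
    X = np.full((la + 1, lb + 1), NEG_INF)
    Y = np.full((la + 1, lb + 1), NEG_INF)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            M[i, j] = max(
                0.0,
                max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
                + sub[i - 1, j - 1],
            )
            X[i, j] = max(
                M[i - 1, j] - first, X[i - 1, j] - rest, Y[i - 1, j] - first
            )
            Y[i, j] = max(
                M[i, j - 1] - first, Y[i, j - 1] - rest, X[i, j - 1] - first
            )
    score = float(M.max())
    if score <= 0:
        return PairwiseAlignment(
            aligned_a="", aligned_b="", score=0.0, mode="local"
        )
    # deterministic best cell: smallest (i, j) in row-major order
    i, j = np.unravel_index(int(np.argmax(M)), M.shape)
    out_a, out_b = [], []
    state = "M"
    tol = 1e-9
    while (i > 0 or j > 0) and not (state == "M" and M[i, j] == 0.0):
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            # M[i, j] > 0 here, so it came from best-predecessor + sub
            target = M[i, j] - sub[i - 1, j - 1]
            i, j = i - 1, j - 1
            for prev, val in (("M", M[i, j]), ("X", X[i, j]), ("Y", Y[i, j])):
                if abs(val - target) <= tol:
                    state = prev
                    break
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append("-")
            here = X[i, j]
            i -= 1
            for prev, val in (
                ("M", M[i, j] - first),
                ("X", X[i, j] - rest),
                ("Y", Y[i, j] - first),
            ):
                if abs(val - here) <= tol:
                    state = prev
                    break
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            here = Y[i, j]
            j -= 1
            for prev, val in (
                ("M", M[i, j] - first),
                ("Y", Y[i, j] - rest),
                ("X", X[i, j] - first),
            ):
                if abs(val - here) <= tol:
                    state = prev
                    break
    return PairwiseAlignment(
        aligned_a="".join(reversed(out_a)),
        aligned_b="".join(reversed(out_b)),
        score=score,
        mode="local",
        start_a=int(i),
        start_b=int(j),
    )


def score_alignment(
    aligned_a: str,
    aligned_b: str,
    m: SubstitutionMatrix,
    g: GapModel | None = None,
    integer: bool = True,
) -> float:
    """Re-score a fixed alignment: substitution scores minus affine gap costs.

    Gap runs are maximal runs of ``-`` in one row; each costs
    open + extend * (L - 1) under the BLAST convention.  A column with gaps
    in both rows is an error.
    """
    if g is None:
        g = GapModel()
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings must have equal length")
    idx, table, floor = _score_table(m, integer)
    total = 0.0
    run_a = run_b = 0  # current gap-run lengths in each row
    for col, (x, y) in enumerate(zip(aligned_a.upper(), aligned_b.upper())):
        if x == "-" and y == "-":
            raise ValueError(f"column {col} has gaps in both rows")
        if x == "-":
            run_a += 1
            total -= g.first if run_a == 1 else g.rest
            run_b = 0
        elif y == "-":
            run_b += 1
            total -= g.first if run_b == 1 else g.rest
            run_a = 0
        else:
            total += _pair_score(x, y, idx, table, floor)
            run_a = run_b = 0
    return total


def _column_maps(aligned: str, start: int = 0) -> dict[int, int]:
    """Map ungapped residue index -> alignment column."""
    out = {}
    pos = start
    for col, ch in enumerate(aligned):
        if ch != "-":
            out[pos] = col
            pos += 1
    return out


def segment_overlap(
    aln: PairwiseAlignment,
    segments_a: Sequence[SegmentDefinition],
    segments_b: Sequence[SegmentDefinition],
) -> dict[str, float]:
    """Per-segment agreement between an alignment and segment annotations.

    For each segment name present in both annotation lists, returns the
    fraction of that segment's residues in sequence a that are aligned
    opposite residues of the same-named segment in sequence b.  Segment
    coordinates refer to ungapped sequence positions.
    """
    by_name_b = {s.name: s for s in segments_b}
    map_a = _column_maps(aln.aligned_a, aln.start_a)
    map_b = _column_maps(aln.aligned_b, aln.start_b)
    col_to_b = {c: p for p, c in map_b.items()}
    out: dict[str, float] = {}
    for seg_a in segments_a:
        if seg_a.name not in by_name_b:
            raise KeyError(f"segment {seg_a.name!r} missing from second annotation")
        seg_b = by_name_b[seg_a.name]
        n = seg_a.width
        hits = 0
        for pos in range(seg_a.start, seg_a.end):
            col = map_a.get(pos)
            if col is None:
                continue  # residue outside the (local) alignment
            bpos = col_to_b.get(col)
            if bpos is not None and seg_b.start <= bpos < seg_b.end:
                hits += 1
        out[seg_a.name] = hits / n if n else 0.0
    return out
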