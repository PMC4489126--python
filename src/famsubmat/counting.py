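"""Block-based substitution-matrix estimation.

This module implements the Henikoff-style block counting pipeline for a
single protein family:

1. every alignment column contributes one count to ``f[a][b]`` for each
   unordered pair of rows carrying standard residues ``a`` and ``b`` (a
   column with ``n`` valid residues contributes ``n(n-1)/2`` pairs);
2. observed pair probabilities  O_ij = f_ij / sum_{i>=j} f_ij;
3. background frequencies       p_i  = O_ii + sum_{j!=i} O_ij / 2;
4. expected pair probabilities  e_ij = 2 p_i p_j (i != j), p_i^2 (i = j);
5. log-odds scores              S_ij = scale * log2(O_ij / e_ij),
   rounded half-away-from-zero to the published integer matrix.

Relative entropy H = sum_{i>=j} O_ij * log2(O_ij / e_ij) (bits) measures how
strongly the matrix separates family alignments from chance; the scaled
convention multiplies by the scale factor (exactly 2x the default here).

Gap characters and ambiguity letters (X, B, Z, U, O) contribute nothing to
pair counts, composition, or conservation denominators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .alphabet import AA_INDEX, AA_ORDER
from .io import AlignmentBlock, MultiBlockAlignment, extract_blocks, filter_redundant
from .matrix import SubstitutionMatrix

__all__ = [
    "PairCountTable",
    "ProbabilityTables",
    "CompositionProfile",
    "ConservationProfile",
    "count_pairs",
    "observed_probabilities",
    "background_frequencies",
    "expected_probabilities",
    "log_odds",
    "relative_entropy",
    "composition",
    "grouped_fraction",
    "column_conservation",
    "build_matrix",
]

_TRI = np.tril_indices(20)  # lower triangle incl. diagonal: the i >= j cells


def _triangle_sum(sym: np.ndarray) -> float:
    """Sum of a symmetric pair table over unordered pairs (i >= j)."""
    return float(sym[_TRI].sum())


@dataclass
class PairCountTable:
    """Symmetric 20x20 table of raw pair tallies f_ij.

    ``counts[i, j] == counts[j, i]`` holds the number of unordered row pairs
    observed for residues i and j; ``total_pairs`` sums the triangle i >= j.
    """

    counts: np.ndarray
    alphabet: str = AA_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (20, 20):
            raise ValueError(f"pair counts must be 20x20, got {self.counts.shape}")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("pair count table must be symmetric")
        if (self.counts < 0).any():
            raise ValueError("pair counts must be non-negative")

    @property
    def total_pairs(self) -> float:
        return _triangle_sum(self.counts)

    def __add__(self, other: "PairCountTable") -> "PairCountTable":
        return PairCountTable(self.counts + other.counts, self.alphabet)


@dataclass
class ProbabilityTables:
    """Observed O_ij, background p_i and expected e_ij tables.

    The symmetric matrices store the unordered-pair probability in both
    mirror cells, so probability mass sums to 1 over the triangle i >= j.
    """

    observed: np.ndarray
    background: np.ndarray
    expected: np.ndarray
    alphabet: str = AA_ORDER

    def validate(self, atol: float = 1e-9) -> None:
        for name, total in (
            ("observed", _triangle_sum(self.observed)),
            ("background", float(self.background.sum())),
            ("expected", _triangle_sum(self.expected)),
        ):
            if abs(total - 1.0) > atol:
                raise ValueError(f"{name} probabilities sum to {total}, not 1")


@dataclass
class CompositionProfile:
    """Residue frequencies over all countable (non-gap, non-ambiguous) positions."""

    fractions: np.ndarray
    n_residues: int
    alphabet: str = AA_ORDER

    def __getitem__(self, residue: str) -> float:
        return float(self.fractions[AA_INDEX[residue.upper()]])

    def as_dict(self) -> dict[str, float]:
        return {aa: float(f) for aa, f in zip(self.alphabet, self.fractions)}


@dataclass
class ConservationProfile:
    """Per-column residue frequencies for one block, gap-excluded denominators.

    ``frequencies[c, i]`` is the fraction of rows carrying residue i among
    rows with a standard residue in column c.  Columns with no standard
    residue are flagged in ``empty_columns`` and excluded from max queries.
    """

    segment_name: str
    frequencies: np.ndarray  # (width, 20)
    depths: np.ndarray  # (width,) countable rows per column
    alphabet: str = AA_ORDER

    @property
    def empty_columns(self) -> np.ndarray:
        return self.depths == 0

    @property
    def max_residue(self) -> list[str | None]:
        """Most frequent residue per column (None for empty columns)."""
        out: list[str | None] = []
        for c in range(self.frequencies.shape[0]):
            if self.depths[c] == 0:
                out.append(None)
            else:
                out.append(self.alphabet[int(np.argmax(self.frequencies[c]))])
        return out

    @property
    def max_fraction(self) -> np.ndarray:
        return self.frequencies.max(axis=1)

    def max_frequency(self, residue: str) -> float:
        """Maximum per-column frequency of one residue within the block."""
        i = AA_INDEX[residue.upper()]
        valid = ~self.empty_columns
        if not valid.any():
            raise ValueError(f"block {self.segment_name!r} has no countable columns")
        return float(self.frequencies[valid, i].max())


def count_pairs(blocks: Iterable[AlignmentBlock]) -> PairCountTable:
    """Tally unordered residue pairs down every column of every block.

    A column with residue multiplicities c_a contributes c_a * c_b pairs to
    f_ab (a != b) and C(c_a, 2) to f_aa.  Gaps and ambiguity letters are
    skipped entirely.
    """
    blocks = list(blocks)
    if not blocks:
        raise ValueError("no alignment blocks to count")
    F = np.zeros((20, 20))
    singles = np.zeros(20)
    for block in blocks:
        codes = block.codes()
        for c in range(codes.shape[1]):
            col = codes[:, c]
            col = col[(col >= 0) & (col < 20)]
            if col.size < 2:
                continue  # no pairs from a 0/1-residue column
            cnt = np.bincount(col, minlength=20).astype(float)
            F += np.outer(cnt, cnt)
            singles += cnt
    # outer() put c_a^2 on the diagonal; unordered self pairs are C(c_a, 2)
    diag = (np.diag(F) - singles) / 2.0
    np.fill_diagonal(F, diag)
    return PairCountTable(counts=F)


def observed_probabilities(table: PairCountTable) -> np.ndarray:
    """O_ij = f_ij / total pairs, symmetric, triangle sums to 1."""
    total = table.total_pairs
    if total <= 0:
        raise ValueError("pair count table is empty (total_pairs = 0)")
    return table.counts / total


def background_frequencies(observed: np.ndarray) -> np.ndarray:
    """p_i = O_ii + sum_{j != i} O_ij / 2; sums to 1."""
    off = observed.sum(axis=1) - np.diag(observed)
    return np.diag(observed) + off / 2.0


def expected_probabilities(background: np.ndarray) -> np.ndarray:
    """e_ij = 2 p_i p_j off-diagonal, p_i^2 on the diagonal."""
    p = np.asarray(background, dtype=float)
    e = 2.0 * np.outer(p, p)
    np.fill_diagonal(e, p * p)
    return e


def _probability_tables(table: PairCountTable) -> ProbabilityTables:
    O = observed_probabilities(table)
    p = background_frequencies(O)
    e = expected_probabilities(p)
    return ProbabilityTables(observed=O, background=p, expected=e, alphabet=table.alphabet)


def log_odds(
    probs: ProbabilityTables,
    scale: float = 2.0,
    floor: float | None = None,
) -> SubstitutionMatrix:
    """Log-odds scores S_ij = scale * log2(O_ij / e_ij).

    Cells never observed (O_ij = 0) have no defined logarithm; they are set
    to ``floor`` (default: the minimum over defined cells, mirroring the
    most-penalised observed exchange).  Integer scores are rounded
    half-away-from-zero.
    """
    O, e = probs.observed, probs.expected
    defined = O > 0
    if (defined & (e <= 0)).any():
        raise ValueError("expected probability 0 where observed > 0")
    S = np.zeros((20, 20))
    S[defined] = scale * np.log2(O[defined] / e[defined])
    if not defined.all():
        fl = float(S[defined].min()) if floor is None else float(floor)
        S[~defined] = fl
    H = relative_entropy(probs, convention="unscaled_bits")
    return SubstitutionMatrix(
        scores_real=S,
        alphabet=probs.alphabet,
        scale_factor=scale,
        log_base=2.0,
        background=probs.background.copy(),
        relative_entropy=H,
        provenance={
            "n_undefined_cells": int((~defined)[_TRI].sum()),
            "floor": None if defined.all() else fl,
        },
    )


def relative_entropy(
    probs: ProbabilityTables, convention: str = "unscaled_bits"
) -> float:
    """Relative entropy of the observed vs expected pair distributions.

    ``unscaled_bits`` (default): H = sum_{i>=j} O_ij log2(O_ij / e_ij),
    skipping O_ij = 0 cells.  ``paper_scaled``: the same sum with the
    2x-scaled scores, i.e. exactly twice the default.  H >= 0 always
    (it is a Kullback-Leibler divergence over unordered pairs).
    """
    if convention not in ("unscaled_bits", "paper_scaled"):
        raise ValueError(f"unknown relative-entropy convention {convention!r}")
    O = probs.observed[_TRI]
    e = probs.expected[_TRI]
    mask = O > 0
    h = float(np.sum(O[mask] * np.log2(O[mask] / e[mask])))
    return 2.0 * h if convention == "paper_scaled" else h


def composition(blocks: Iterable[AlignmentBlock]) -> CompositionProfile:
    """Residue frequencies over all non-gap, non-ambiguous block positions."""
    blocks = list(blocks)
    if not blocks:
        raise ValueError("no alignment blocks")
    counts = np.zeros(20)
    for block in blocks:
        codes = block.codes().ravel()
        codes = codes[(codes >= 0) & (codes < 20)]
        counts += np.bincount(codes, minlength=20)
    total = counts.sum()
    if total == 0:
        raise ValueError("blocks contain no countable residues")
    return CompositionProfile(fractions=counts / total, n_residues=int(total))


def grouped_fraction(profile: CompositionProfile, residues: Iterable[str]) -> float:
    """Summed composition of a residue group (e.g. charged/polar R,K,H,D,E,N,Q)."""
    total = 0.0
    for r in residues:
        r = r.upper()
        if r not in AA_INDEX:
            raise KeyError(f"unknown residue letter {r!r}")
        total += profile.fractions[AA_INDEX[r]]
    return float(total)


def column_conservation(block: AlignmentBlock) -> ConservationProfile:
    """Per-column residue frequencies over rows with a standard residue."""
    codes = block.codes()
    width = codes.shape[1]
    freqs = np.zeros((width, 20))
    depths = np.zeros(width, dtype=int)
    for c in range(width):
        col = codes[:, c]
        col = col[(col >= 0) & (col < 20)]
        depths[c] = col.size
        if col.size:
            freqs[c] = np.bincount(col, minlength=20) / col.size
    return ConservationProfile(
        segment_name=block.segment.name, frequencies=freqs, depths=depths
    )


def build_matrix(
    aln: MultiBlockAlignment,
    redundancy: float | None = 0.90,
    scale: float = 2.0,
    pseudocount: float = 0.0,
    floor: float | None = None,
) -> SubstitutionMatrix:
    """Full pipeline: redundancy filter, block extraction, counting, log-odds.

    Parameters
    ----------
    redundancy : identity threshold for the greedy filter, or None to skip.
    scale : score scale factor (half-bit scores by default).
    pseudocount : Laplace count added to every unordered pair cell of f
        before normalisation (0 preserves the raw counts; zero cells then
        take the floor score).
    floor : explicit floor score for unobserved cells (default: the minimum
        over defined cells).
    """
    n_input = aln.n_sequences
    if redundancy is not None:
        aln = filter_redundant(aln, threshold=redundancy)
    blocks = extract_blocks(aln)
    counts = count_pairs(blocks)
    if pseudocount:
        counts = PairCountTable(counts.counts + pseudocount, counts.alphabet)
    probs = _probability_tables(counts)
    m = log_odds(probs, scale=scale, floor=floor)
    m.provenance.update(
        n_sequences_input=n_input,
        n_sequences_used=aln.n_sequences,
        n_blocks=len(blocks),
        total_pairs=counts.total_pairs,
        redundancy_threshold=redundancy,
        pseudocount=pseudocount,
        relative_entropy_scaled=relative_entropy(probs, "paper_scaled"),
    )
    return m
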