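"""The SubstitutionMatrix container and its text-file format.

Matrices are written in the NCBI/EMBOSS scoring-matrix layout — comment
lines starting ``#``, a column-label row, then one labelled row of integers
per residue — so they can be consumed by standard alignment tools and read
back by :func:`read_matrix`.  Background frequencies and relative entropy,
when known, travel in structured header comments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .alphabet import AA_ORDER

__all__ = ["SubstitutionMatrix", "read_matrix", "write_matrix", "MatrixFormatError"]


class MatrixFormatError(ValueError):
    """Matrix file is not a square, symmetric, labelled integer table."""


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (sign-symmetric)."""
    return np.where(x >= 0, np.floor(x + 0.5), np.ceil(x - 0.5))


@dataclass
class SubstitutionMatrix:
    """A symmetric residue-pair scoring matrix.

    Attributes
    ----------
    alphabet : str
        Residue order of rows/columns (default NCBI order).
    scores_real : (n, n) float array
        Unrounded log-odds scores.
    scores_int : (n, n) int array
        ``scores_real`` rounded half-away-from-zero.
    scale_factor, log_base : float
        Score = scale_factor * log_base-logarithm of observed/expected.
    background : (n,) float array or None
        Residue background frequencies p_i, when derived from data.
    relative_entropy : float or None
        H in bits (unscaled convention).
    provenance : dict
        Free-form metadata (source counts, options used).
    """

    scores_real: np.ndarray
    alphabet: str = AA_ORDER
    scale_factor: float = 2.0
    log_base: float = 2.0
    background: np.ndarray | None = None
    relative_entropy: float | None = None
    provenance: dict = field(default_factory=dict)
    scores_int: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.scores_real = np.asarray(self.scores_real, dtype=float)
        n = len(self.alphabet)
        if self.scores_real.shape != (n, n):
            raise MatrixFormatError(
                f"scores must be {n}x{n} for alphabet {self.alphabet!r}, "
                f"got {self.scores_real.shape}"
            )
        if not np.allclose(self.scores_real, self.scores_real.T, atol=1e-9):
            raise MatrixFormatError("substitution matrix must be symmetric")
        if self.scores_int is None:
            self.scores_int = round_half_away(self.scores_real).astype(int)
        else:
            self.scores_int = np.asarray(self.scores_int, dtype=int)

    @classmethod
    def from_int_scores(
        cls, scores: np.ndarray, alphabet: str = AA_ORDER, **kw
    ) -> "SubstitutionMatrix":
        scores = np.asarray(scores, dtype=float)
        return cls(scores_real=scores, alphabet=alphabet, **kw)

    @property
    def n(self) -> int:
        return len(self.alphabet)

    def index(self, residue: str) -> int:
        try:
            return self.alphabet.index(residue.upper())
        except ValueError:
            raise KeyError(f"residue {residue!r} not in matrix alphabet") from None

    @property
    def min_score(self) -> int:
        """Floor score, used for ambiguity letters in alignment."""
        return int(self.scores_int.min())

    def score(self, a: str, b: str, integer: bool = True) -> float:
        """Score one residue pair; ambiguity letters score the matrix floor."""
        table = self.scores_int if integer else self.scores_real
        try:
            return float(table[self.index(a), self.index(b)])
        except KeyError:
            return float(self.min_score if integer else self.scores_real.min())

    def lookup(self, integer: bool = True) -> Mapping[tuple[str, str], float]:
        """Dict view {(a, b): score} over the full table."""
        table = self.scores_int if integer else self.scores_real
        return {
            (x, y): float(table[i, j])
            for i, x in enumerate(self.alphabet)
            for j, y in enumerate(self.alphabet)
        }

    def as_dataframe(self, integer: bool = True):
        import pandas as pd

        table = self.scores_int if integer else self.scores_real
        labels = list(self.alphabet)
        return pd.DataFrame(table, index=labels, columns=labels)


def write_matrix(
    m: SubstitutionMatrix, path: str | Path, comments: list[str] | None = None
) -> None:
    """Write the integer matrix in NCBI/EMBOSS text layout."""
    lines = []
    for c in comments or []:
        lines.append(f"# {c}")
    lines.append(f"# scale_factor: {m.scale_factor:g}  log_base: {m.log_base:g}")
    if m.relative_entropy is not None:
        lines.append(f"# relative_entropy_bits: {m.relative_entropy:.6f}")
    if m.background is not None:
        bg = " ".join(f"{aa}={p:.6f}" for aa, p in zip(m.alphabet, m.background))
        lines.append(f"# background: {bg}")
    lines.append("   " + "  ".join(m.alphabet))
    for i, aa in enumerate(m.alphabet):
        row = " ".join(f"{v:3d}" for v in m.scores_int[i])
        lines.append(f"{aa} {row}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_matrix(path: str | Path) -> SubstitutionMatrix:
    """Read an NCBI/EMBOSS-format scoring matrix.

    Background frequencies and relative entropy are recovered from header
    comments when present (as written by :func:`write_matrix`); otherwise
    they are absent.  Lowercase labels are accepted and uppercased.
    """
    background = None
    rel_ent = None
    scale, base = 2.0, 2.0
    labels: list[str] | None = None
    rows: list[list[int]] = []
    row_labels: list[str] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("background:"):
                pairs = body.split(":", 1)[1].split()
                background = np.array([float(p.split("=")[1]) for p in pairs])
            elif body.startswith("relative_entropy_bits:"):
                rel_ent = float(body.split(":", 1)[1])
            elif body.startswith("scale_factor:"):
                toks = body.replace(":", " ").split()
                scale = float(toks[toks.index("scale_factor") + 1])
                if "log_base" in toks:
                    base = float(toks[toks.index("log_base") + 1])
            continue
        toks = line.split()
        if labels is None:
            if not all(len(t) == 1 and t.isalpha() for t in toks):
                raise MatrixFormatError(f"expected column-label row, got {raw!r}")
            labels = [t.upper() for t in toks]
            continue
        row_labels.append(toks[0].upper())
        try:
            rows.append([int(v) for v in toks[1:]])
        except ValueError as exc:
            raise MatrixFormatError(f"non-integer score in row {raw!r}") from exc
    if labels is None or not rows:
        raise MatrixFormatError(f"no matrix table found in {path}")
    n = len(labels)
    if len(rows) != n or any(len(r) != n for r in rows):
        raise MatrixFormatError(
            f"matrix table is not square: {len(labels)} columns, "
            f"{len(rows)} rows of widths {sorted({len(r) for r in rows})}"
        )
    if row_labels != labels:
        raise MatrixFormatError("row labels do not match column labels")
    scores = np.array(rows, dtype=float)
    if not np.array_equal(scores, scores.T):
        raise MatrixFormatError("matrix table is not symmetric")
    return SubstitutionMatrix(
        scores_real=scores,
        alphabet="".join(labels),
        scale_factor=scale,
        log_base=base,
        background=background,
        relative_entropy=rel_ent,
        provenance={"source": str(path)},
    )
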