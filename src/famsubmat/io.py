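"""Aligned-sequence input, segment blocks and redundancy filtering.

Alignments are read with Bio.AlignIO (FASTA or Clustal dialects) into a
:class:`MultiBlockAlignment`, the container every downstream stage consumes.
Segment definitions use 0-based half-open column ranges internally; the
plain-text segment table (and the CLI) speak 1-based inclusive coordinates,
the usual convention in sequence annotation, and are converted on read.

Redundancy filtering is a greedy keep-first pass: a sequence is dropped when
its percent identity to any previously kept sequence exceeds the threshold
(default 0.90, i.e. ">90 % identical" sequences are excluded).  Identity is
computed over pairwise positions where neither sequence has a gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import ALLOWED, encode

__all__ = [
    "SequenceRecord",
    "SegmentDefinition",
    "AlignmentBlock",
    "MultiBlockAlignment",
    "read_alignment",
    "write_alignment",
    "read_segments",
    "write_segments",
    "extract_blocks",
    "percent_identity",
    "filter_redundant",
]


class AlignmentShapeError(ValueError):
    """Sequences in an alignment do not all have the same length."""


class CharacterError(ValueError):
    """A sequence contains a character outside the allowed alphabet."""


class ConfigurationError(ValueError):
    """Segment definitions are missing, overlapping or out of bounds."""


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence: identifier plus gapped residue string (uppercase)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "residues", self.residues.upper())
        for pos, ch in enumerate(self.residues):
            if ch not in ALLOWED:
                raise CharacterError(
                    f"illegal character {ch!r} at position {pos} in sequence {self.id!r}"
                )


@dataclass(frozen=True)
class SegmentDefinition:
    """A named alignment-column range, 0-based half-open [start, end)."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("segment name must be nonempty")
        if not (0 <= self.start < self.end):
            raise ConfigurationError(
                f"segment {self.name!r}: need 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignmentBlock:
    """Rows of one segment: the counting substrate for pair frequencies."""

    segment: SegmentDefinition
    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError(f"block {self.segment.name!r} needs at least 2 rows")
        w = self.segment.width
        for rid, rseq in self.rows:
            if len(rseq) != w:
                raise AlignmentShapeError(
                    f"block {self.segment.name!r}: row {rid!r} has length "
                    f"{len(rseq)}, expected {w}"
                )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return self.segment.width

    def codes(self) -> np.ndarray:
        """(n_rows, width) int8 matrix of residue codes."""
        return np.vstack([encode(r) for _, r in self.rows])


@dataclass
class MultiBlockAlignment:
    """Full alignment plus its segment definitions."""

    records: list[SequenceRecord]
    segments: list[SegmentDefinition] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentShapeError("alignment has no sequences")
        w = len(self.records[0].residues)
        for rec in self.records:
            if len(rec.residues) != w:
                raise AlignmentShapeError(
                    f"sequence {rec.id!r} has length {len(rec.residues)}, "
                    f"expected {w} (all aligned sequences must match)"
                )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate sequence id {dup!r}")
        self._check_segments()

    def _check_segments(self) -> None:
        w = self.width
        spans: list[tuple[int, int, str]] = []
        for seg in self.segments:
            if seg.end > w:
                raise ConfigurationError(
                    f"segment {seg.name!r} [{seg.start}, {seg.end}) exceeds "
                    f"alignment width {w}"
                )
            spans.append((seg.start, seg.end, seg.name))
        spans.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ConfigurationError(f"segments {n1!r} and {n2!r} overlap")

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    @property
    def width(self) -> int:
        return len(self.records[0].residues)

    def codes(self) -> np.ndarray:
        """(n_sequences, width) int8 code matrix."""
        return np.vstack([encode(r.residues) for r in self.records])


def _to_biopython(aln: MultiBlockAlignment) -> MultipleSeqAlignment:
    return MultipleSeqAlignment(
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in aln.records
    )


def read_alignment(
    path: str | Path,
    fmt: str = "fasta",
    segments: Sequence[SegmentDefinition] | None = None,
) -> MultiBlockAlignment:
    """Read an aligned FASTA or Clustal file.

    Parameters
    ----------
    path : file path
    fmt : ``"fasta"`` or ``"clustal"``
    segments : optional segment definitions to attach

    Raises
    ------
    AlignmentShapeError
        if sequences are not all the same length.
    CharacterError
        if a sequence contains a character outside the allowed alphabet,
        naming the offender and its position.
    """
    if fmt not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {fmt!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"alignment file not found: {path}")
    # Bio.AlignIO enforces equal lengths for clustal; for fasta we parse
    # record-wise so a ragged file raises our shape error, not biopython's.
    if fmt == "fasta":
        from Bio import SeqIO

        records = [
            SequenceRecord(id=rec.id, residues=str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")
        ]
        return MultiBlockAlignment(records=records, segments=list(segments or []))
    msa = AlignIO.read(str(path), fmt)
    records = [SequenceRecord(id=rec.id, residues=str(rec.seq)) for rec in msa]
    return MultiBlockAlignment(records=records, segments=list(segments or []))


def write_alignment(aln: MultiBlockAlignment, path: str | Path, fmt: str = "fasta") -> None:
    """Write the alignment in FASTA or Clustal format."""
    if fmt not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {fmt!r}")
    AlignIO.write(_to_biopython(aln), str(path), fmt)


def read_segments(path: str | Path) -> list[SegmentDefinition]:
    """Read a segment table: TSV rows ``name <tab> start <tab> end``.

    Coordinates in the file are 1-based inclusive (the annotation convention);
    they are converted to the 0-based half-open ranges used internally.
    Lines starting with ``#`` and blank lines are skipped; a ``name start end``
    header row is tolerated.
    """
    segs: list[SegmentDefinition] = []
    first_data = True
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", "\t").split()
        if len(parts) != 3:
            raise ConfigurationError(
                f"{path}:{lineno}: expected 'name start end', got {raw!r}"
            )
        name, s, e = parts
        if first_data:
            first_data = False
            if not (s.lstrip("-").isdigit() and e.lstrip("-").isdigit()):
                continue  # header row
        try:
            start1, end1 = int(s), int(e)
        except ValueError as exc:
            raise ConfigurationError(f"{path}:{lineno}: non-integer coordinate") from exc
        if start1 < 1 or end1 < start1:
            raise ConfigurationError(
                f"{path}:{lineno}: need 1 <= start <= end (1-based inclusive), "
                f"got {start1}..{end1}"
            )
        segs.append(SegmentDefinition(name=name, start=start1 - 1, end=end1))
    if not segs:
        raise ConfigurationError(f"no segments found in {path}")
    return segs


def write_segments(segments: Iterable[SegmentDefinition], path: str | Path) -> None:
    """Write a segment table (1-based inclusive, as read_segments expects)."""
    with open(path, "w") as fh:
        fh.write("name\tstart\tend\n")
        for seg in segments:
            fh.write(f"{seg.name}\t{seg.start + 1}\t{seg.end}\n")


def extract_blocks(aln: MultiBlockAlignment) -> list[AlignmentBlock]:
    """Slice the alignment into one :class:`AlignmentBlock` per segment.

    Row order is preserved; columns outside every segment are discarded.
    """
    if not aln.segments:
        raise ConfigurationError("alignment has no segment definitions")
    blocks = []
    for seg in aln.segments:
        rows = tuple((r.id, r.residues[seg.start : seg.end]) for r in aln.records)
        blocks.append(AlignmentBlock(segment=seg, rows=rows))
    return blocks


def percent_identity(a: str, b: str) -> float:
    """Fraction of identical residues over positions ungapped in both sequences.

    Positions where either sequence has a gap are excluded from both the
    numerator and the denominator.  Returns 0.0 when no comparable positions
    exist.
    """
    if len(a) != len(b):
        raise AlignmentShapeError(
            f"cannot compare sequences of lengths {len(a)} and {len(b)}"
        )
    ca, cb = encode(a.upper()), encode(b.upper())
    comparable = (ca != -1) & (cb != -1)
    n = int(comparable.sum())
    if n == 0:
        return 0.0
    return float(((ca == cb) & comparable).sum()) / n


def filter_redundant(
    aln: MultiBlockAlignment, threshold: float = 0.90
) -> MultiBlockAlignment:
    """Greedy keep-first redundancy filter.

    A record is kept iff its identity to every previously kept record is
    <= ``threshold``; strictly-greater-than-threshold is excluded.  Input
    order of the kept records is preserved.  The pass is idempotent.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    codes = aln.codes()
    ungapped = codes != -1
    kept_idx: list[int] = []
    for i in range(aln.n_sequences):
        if kept_idx:
            prev = codes[kept_idx]
            comp = ungapped[kept_idx] & ungapped[i]
            n = comp.sum(axis=1)
            matches = ((prev == codes[i]) & comp).sum(axis=1)
            ident = np.where(n > 0, matches / np.maximum(n, 1), 0.0)
            if (ident > threshold).any():
                continue
        kept_idx.append(i)
    return MultiBlockAlignment(
        records=[aln.records[i] for i in kept_idx],
        segments=list(aln.segments),
    )
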