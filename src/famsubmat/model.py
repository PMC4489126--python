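"""Model/Results surface over the block-counting pipeline.

`SubstitutionMatrixModel` holds the data (a multi-block alignment) and the
estimation options; `fit()` runs redundancy filtering, block extraction,
pair counting and log-odds scoring, and returns a
`SubstitutionMatrixResults` carrying the matrix, the probability tables,
relative entropy, composition and conservation diagnostics, and a
`summary()` table.  Clustering, projection and downstream alignment hang
off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import counting
from .analysis import Dendrogram, DistanceMatrix, Projection, score_to_distance, upgma, classical_mds
from .counting import (
    CompositionProfile,
    ConservationProfile,
    PairCountTable,
    ProbabilityTables,
)
from .io import (
    AlignmentBlock,
    MultiBlockAlignment,
    extract_blocks,
    filter_redundant,
    read_alignment,
    read_segments,
)
from .matrix import SubstitutionMatrix

__all__ = ["SubstitutionMatrixModel", "SubstitutionMatrixResults"]


class SubstitutionMatrixModel:
    """Log-odds substitution-matrix estimator for one protein family.

    Parameters
    ----------
    alignment : MultiBlockAlignment
        Aligned family sequences with segment (block) definitions.
    redundancy : float or None
        Identity threshold for the greedy redundancy filter; records more
        than this fraction identical to a kept record are excluded.  None
        disables filtering.
    scale : float
        Score scale factor; 2 gives half-bit scores.
    pseudocount : float
        Laplace count added to every pair cell before normalisation.
    floor : float or None
        Score assigned to never-observed pairs (default: minimum over
        observed cells).

    Examples
    --------
    >>> model = SubstitutionMatrixModel.from_files("aln.fasta", "tms.tsv")
    >>> res = model.fit()
    >>> res.relative_entropy
    0.65...
    >>> print(res.summary())
    """

    def __init__(
        self,
        alignment: MultiBlockAlignment,
        redundancy: float | None = 0.90,
        scale: float = 2.0,
        pseudocount: float = 0.0,
        floor: float | None = None,
    ) -> None:
        if not alignment.segments:
            raise ValueError("alignment needs segment definitions to form blocks")
        self.alignment = alignment
        self.redundancy = redundancy
        self.scale = scale
        self.pseudocount = pseudocount
        self.floor = floor

    @classmethod
    def from_files(
        cls,
        alignment_path: str | Path,
        segments_path: str | Path,
        fmt: str = "fasta",
        **options,
    ) -> "SubstitutionMatrixModel":
        """Build the model from an aligned FASTA/Clustal file and a segment table."""
        segments = read_segments(segments_path)
        aln = read_alignment(alignment_path, fmt=fmt, segments=segments)
        return cls(aln, **options)

    def fit(self) -> "SubstitutionMatrixResults":
        """Run the pipeline and return the fitted results."""
        aln = self.alignment
        if self.redundancy is not None:
            aln = filter_redundant(aln, threshold=self.redundancy)
        blocks = extract_blocks(aln)
        counts = counting.count_pairs(blocks)
        if self.pseudocount:
            counts = PairCountTable(
                counts.counts + self.pseudocount, counts.alphabet
            )
        observed = counting.observed_probabilities(counts)
        background = counting.background_frequencies(observed)
        expected = counting.expected_probabilities(background)
        probs = ProbabilityTables(
            observed=observed, background=background, expected=expected
        )
        matrix = counting.log_odds(probs, scale=self.scale, floor=self.floor)
        matrix.provenance.update(
            n_sequences_input=self.alignment.n_sequences,
            n_sequences_used=aln.n_sequences,
            n_blocks=len(blocks),
            total_pairs=counts.total_pairs,
            redundancy_threshold=self.redundancy,
            pseudocount=self.pseudocount,
            relative_entropy_scaled=counting.relative_entropy(probs, "paper_scaled"),
        )
        return SubstitutionMatrixResults(
            model=self,
            filtered_alignment=aln,
            blocks=blocks,
            pair_counts=counts,
            probabilities=probs,
            matrix=matrix,
        )


@dataclass
class SubstitutionMatrixResults:
    """Fitted substitution matrix with its diagnostics."""

    model: SubstitutionMatrixModel
    filtered_alignment: MultiBlockAlignment
    blocks: list[AlignmentBlock]
    pair_counts: PairCountTable
    probabilities: ProbabilityTables
    matrix: SubstitutionMatrix

    # -- scalar diagnostics -------------------------------------------------
    @property
    def n_sequences(self) -> int:
        """Sequences used after redundancy filtering."""
        return self.filtered_alignment.n_sequences

    @property
    def relative_entropy(self) -> float:
        """H in bits (unscaled convention)."""
        return counting.relative_entropy(self.probabilities, "unscaled_bits")

    @property
    def relative_entropy_scaled(self) -> float:
        """H under the scaled-score convention (exactly 2x the default)."""
        return counting.relative_entropy(self.probabilities, "paper_scaled")

    @property
    def background(self) -> np.ndarray:
        return self.probabilities.background

    # -- composition and conservation ---------------------------------------
    def composition(self) -> CompositionProfile:
        """Residue composition over all block positions."""
        return counting.composition(self.blocks)

    def grouped_composition(self, residues) -> float:
        """Summed composition of a residue group."""
        return counting.grouped_fraction(self.composition(), residues)

    def conservation(self, segment: str | None = None):
        """ConservationProfile for one segment, or dict of all of them."""
        profiles = {
            b.segment.name: counting.column_conservation(b) for b in self.blocks
        }
        if segment is None:
            return profiles
        if segment not in profiles:
            raise KeyError(f"unknown segment {segment!r}")
        return profiles[segment]

    def max_conservation(self, segment: str, residue: str) -> float:
        """Maximum per-column frequency of ``residue`` within ``segment``."""
        return self.conservation(segment).max_frequency(residue)

    # -- downstream analyses -------------------------------------------------
    def to_distance(self, method: str = "diagonal_deficit") -> DistanceMatrix:
        return score_to_distance(self.matrix, method=method)

    def upgma(self, method: str = "diagonal_deficit") -> Dendrogram:
        """UPGMA residue dendrogram from the fitted matrix."""
        return upgma(self.to_distance(method))

    def mds(self, k: int = 2, method: str = "diagonal_deficit") -> Projection:
        """Classical-MDS residue projection from the fitted matrix."""
        return classical_mds(self.to_distance(method), k=k)

    # -- reporting ------------------------------------------------------------
    def summary(self) -> str:
        """Human-readable fit summary in a statsmodels-like layout."""
        m = self.matrix
        prov = m.provenance
        comp = self.composition()
        lines = []
        lines.append("Substitution-matrix estimation (block log-odds)")
        lines.append("=" * 56)
        lines.append(f"{'Sequences (input)':34s}{prov.get('n_sequences_input', '-'):>12}")
        lines.append(f"{'Sequences (after filter)':34s}{self.n_sequences:>12}")
        lines.append(f"{'Redundancy threshold':34s}{str(self.model.redundancy):>12}")
        lines.append(f"{'Blocks':34s}{len(self.blocks):>12}")
        lines.append(f"{'Residue pairs counted':34s}{prov.get('total_pairs', 0):>12.0f}")
        lines.append(f"{'Scale factor':34s}{m.scale_factor:>12g}")
        lines.append(f"{'Pseudocount':34s}{self.model.pseudocount:>12g}")
        lines.append(f"{'Relative entropy H (bits)':34s}{self.relative_entropy:>12.4f}")
        lines.append(
            f"{'Relative entropy (scaled)':34s}{self.relative_entropy_scaled:>12.4f}"
        )
        lines.append("-" * 56)
        lines.append("Composition (%)        Background p_i (%)")
        for aa in m.alphabet:
            i = m.alphabet.index(aa)
            lines.append(
                f"  {aa}  {100 * comp.fractions[i]:6.2f}            "
                f"{100 * self.background[i]:6.2f}"
            )
        lines.append("=" * 56)
        return "\n".join(lines)
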