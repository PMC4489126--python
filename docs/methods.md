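# Methods

## Estimator

The matrix is a block log-odds estimator in the Henikoff tradition, applied
to one protein family. The counting substrate is a set of alignment blocks:
gapped, equal-width row sets restricted to named column ranges (segments).
Every column contributes one count per unordered pair of rows whose
characters are both standard residues; with residue multiplicities
$c_a$ in a column this is $c_a c_b$ counts for $a \ne b$ and
$\binom{c_a}{2}$ for $a = b$, i.e. $n(n-1)/2$ pairs for a column with $n$
countable rows. Gaps and ambiguity letters (X, B, Z, U, O) contribute
nothing — the equations are defined over the 20 standard residues only —
but ambiguity letters remain legal input everywhere.

From the count table $f$:

- observed pair probabilities $O_{ij} = f_{ij} / \sum_{i\ge j} f_{ij}$
  (mass normalised over unordered pairs);
- background frequencies $p_i = O_{ii} + \sum_{j\ne i} O_{ij}/2$;
- expected pair probabilities $e_{ij} = 2 p_i p_j$ for $i \ne j$, $p_i^2$
  on the diagonal (both sum to 1 over the triangle by construction);
- scores $S_{ij} = s \cdot \log_2(O_{ij}/e_{ij})$ with scale $s = 2$
  (half-bit units) by default, kept both unrounded and rounded to integers.

No sequence weighting is applied; redundancy is handled instead by the
identity filter below, which matches how single-family block sets are
usually curated.

### Conventions and numerical choices

- **Relative entropy.** The default convention is unscaled bits,
  $H = \sum_{i\ge j} O_{ij} \log_2(O_{ij}/e_{ij})$, skipping $O_{ij}=0$
  cells; this is the convention under which the classic published values
  (e.g. BLOSUM62's $H \approx 0.70$) are stated. A `paper_scaled` variant
  multiplies by the scale factor (exactly 2× here), matching texts that
  define $H$ through the scaled scores; both are recorded in provenance.
  $H$ is always computed from the unrounded scores — rounding first cannot
  reproduce four-decimal entropy values. $H \ge 0$ always, being a KL
  divergence over unordered pairs.
- **Zero cells.** $f_{ij} = 0$ leaves $\log O_{ij}$ undefined. Default
  policy: no pseudocount; the cell's score is floored at the minimum over
  defined cells (the most-penalised observed exchange), which preserves the
  estimator exactly where counts exist while keeping the matrix usable for
  alignment. A Laplace pseudocount on $f$ (every unordered cell) is
  available as an option.
- **Rounding.** Half-away-from-zero: symmetric for positive and negative
  scores and deterministic, which plain "nearest integer" leaves
  under-specified at `.5`.
- **Coordinates.** Internally all column ranges are 0-based half-open;
  the segment-table file format and the CLI use 1-based inclusive
  coordinates (the annotation convention) and convert on read.

## Redundancy filter

Percent identity between two aligned rows excludes positions gapped in
either row from both numerator and denominator (0 when no comparable
positions exist) — the standard definition for gapped alignments, and
stable under the small indels such curated TM alignments contain. The
filter is a greedy keep-first pass in input order: a record is kept iff its
identity to every previously kept record is ≤ the threshold (default 0.90,
so strictly "> 90 % identical" is excluded). Greedy keep-first was chosen
over clustering because it is deterministic, order-documented and
idempotent. The identity screen is computed over the supplied (block-only)
alignment columns.

## Matrix analyses

- **Difference matrix**: cell-wise subtraction of integer scores, alphabets
  required to match.
- **Score → distance**: the literature rarely states this transform, so two
  are provided. Default `diagonal_deficit`,
  $d_{ij} = S_{ii} + S_{jj} - 2 S_{ij}$ floored at 0, is monotone-decreasing
  in the log-odds and zero on self; `correlation`
  ($1 -$ Pearson correlation of matrix rows) is the common alternative.
  Cluster *topology* is the comparable output across transforms; merge
  heights are transform-specific and no claim is attached to them.
- **UPGMA**: unweighted arithmetic-mean linkage; merge height is half the
  merged distance, so cophenetic distances are ultrametric. Ties are broken
  by the lexicographically smallest pair of cluster labels (a cluster is
  labelled by its smallest member), making output deterministic. The
  implementation is cross-checked in the tests against SciPy's
  average-linkage on tie-free random inputs.
- **Classical MDS** (Torgerson): double-centre $-\tfrac12 D^2$,
  eigendecompose, keep the top-$k$ positive eigenpairs; axis signs are fixed
  by making each axis's largest-magnitude coordinate positive, so output is
  reproducible. If fewer than $k$ eigenvalues are positive the embedding is
  truncated and flagged.

## Pairwise alignment

Needleman–Wunsch–Gotoh (global) and Smith–Waterman–Gotoh (local) under any
symmetric matrix. Gap costs use the BLAST existence/extension convention —
a run of length $L$ costs $\mathrm{open} + \mathrm{ext}\,(L-1)$ — because
that is how the defaults (open 15, extend 2) are stated for database-search
tools; the `open + ext·L` convention is available as an option. Integer
scores are used by default, matching how published matrices are consumed.
Traceback tie-breaks are fixed (diagonal, then gap in the second sequence,
then gap in the first) so alignments are deterministic. Ambiguity letters
score the matrix floor. `segment_overlap` quantifies how well an alignment
places annotated segments: for each shared segment name, the fraction of
the first sequence's segment residues aligned opposite residues of the
same-named segment in the second — the quantitative surrogate for "the
helices are aligned correctly".

Correctness is established against two independent references: explicit
enumeration of the complete gapped-alignment space (lengths ≤ 5) and a
memoised recursion over (position, previous move) computing the same
maximum (lengths ≤ 8), both scoring alignments by an explicit column walk.

## Synthetic generator

A column-anchor model, not a phylogenetic simulator: per column an anchor
residue is drawn from the target composition; each row independently keeps
the anchor with the column's conservation probability or draws a
replacement $r$ with probability $\propto$ exchangeability$[a,r] \cdot
\pi_r$ — the standard reversible-model factorisation of a rate into a
symmetric exchangeability and stationary frequencies, which keeps the
exchangeability table symmetric and the realized composition close to the
target. This reproduces the two features the block statistics depend on
(compositional bias, per-column conservation) with minimal machinery.

Defaults encode the study conditions the package is aimed at: 1019
sequences; seven contiguous helix blocks of widths 32/31/35/27/33/34/29
(all under 40 columns, typical class-A TM helix block widths); the family's
TM residue composition (leucine 14.1 %, valine 9.2 %, cysteine 3.6 %,
glycine 4.6 %; charged/polar R,K,H,D,E,N,Q summing to 19.6 %); one pinned
near-invariant motif column per helix at the family's observed conservation
(N 98 % in helix 1, D 93 % in 2, R 95 % in 3, W 96 % in 4, P 76/98/93 % in
5/6/7), placed mid-block; background column conservation 0.70, a realistic
level for moderately conserved TM columns; and a smoothly graded
exchangeability kernel $s_{ij} = \exp(-|h_i - h_j|/1.5)$ over Kyte–Doolittle
hydropathy, with an irrational-spaced jitter added to tied hydropathy
values so all 190 off-diagonal ranks are distinct (a requirement for
rank-based parameter recovery). All randomness flows from a single seed.

What the generator does **not** emulate: phylogenetic correlation between
rows (rows are i.i.d. given the column plan), rate variation across
lineages, indel processes (no gaps are generated), or long-range
correlation between columns. Passing tests therefore demonstrate
correctness of the estimator and analyses under compositional bias and
conservation structure — not robustness to tree-structured data.

`expected_composition` and `composition_standard_error` give the analytic
law of the realized composition and its sampling error (anchor-level
between-column variance plus within-column multinomial variance), which is
what the composition round-trip test checks against; the realized
composition is also verified to stay within 0.02 of the family target under
the default kernel.

## Parameter recovery

`recovery_experiment` simulates, rebuilds the matrix, and reports the
Spearman correlation between generating off-diagonal exchangeabilities and
recovered off-diagonal real-valued scores, restricted to observed cells
(floor cells carry no signal; with an identity exchangeability none exist
and the correlation is reported as undefined). At 500 sequences × 200
columns (8 blocks of 25) with the graded kernel and conservation 0.70 the
recovery is ρ ≈ 0.98; the acceptance suite asserts ρ > 0.9. The kernel's
decay scale (1.5) and the conservation level were fixed by a single
calibration run of this oracle before the thresholds were frozen.

## Problem sizes used in the checks

Equation fidelity runs on 1000 random blocks of ≤ 6 rows × ≤ 5 columns
(counts exact, probabilities/scores to 1e-12); aligner optimality on 10⁴
random pairs of lengths ≤ 8 against the complete alignment space; MDS on a
planted 20-point planar configuration (Procrustes error < 1e-8); UPGMA on
a hand-worked 3-leaf matrix (heights 1 and 3) and random matrices
(ultrametricity); recovery at 500 × 200 as above. The acceptance script
additionally fits the full default study-scale alignment (1019 × 221).

## Known limitations

- The estimator assumes the blocks are correctly aligned; it has no notion
  of alignment uncertainty.
- No sequence weighting means deep, unevenly sampled families rely entirely
  on the identity filter to control lineage over-representation.
- The zero-cell floor is a pragmatic device, not an estimate; matrices
  built from small block sets will have many floored cells and should be
  used with a pseudocount instead.
- UPGMA merge heights depend on the score→distance transform chosen;
  only topology should be compared across matrices.
- The local aligner's empty result (score 0) for all-negative score
  landscapes returns empty aligned strings by design.
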