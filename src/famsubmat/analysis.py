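"""Matrix comparison, residue clustering and low-dimensional projection.

Two matrices trained on different data sets are compared cell-wise with a
difference matrix.  To ask which residues a matrix treats as exchangeable,
scores are turned into dissimilarities and the 20 residues are clustered
with UPGMA and embedded with classical (Torgerson) multidimensional scaling.

The score-to-distance transform is configurable because published work is
not uniform here: ``diagonal_deficit`` (default) uses
d_ij = S_ii + S_jj - 2 S_ij, which is monotone-decreasing in the log-odds
and zero on self; ``correlation`` uses one minus the Pearson correlation of
matrix rows, a common alternative.  Cluster topologies, not merge heights,
are the comparable output across transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .matrix import SubstitutionMatrix

__all__ = [
    "DifferenceMatrix",
    "DistanceMatrix",
    "Dendrogram",
    "DendrogramNode",
    "Projection",
    "difference_matrix",
    "score_to_distance",
    "upgma",
    "classical_mds",
]


@dataclass
class DifferenceMatrix:
    """Cell-wise A - B on integer scores, with the operand labels."""

    values: np.ndarray
    label_a: str
    label_b: str
    alphabet: str

    def as_dataframe(self):
        import pandas as pd

        labels = list(self.alphabet)
        return pd.DataFrame(self.values, index=labels, columns=labels)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative residue dissimilarities with zero diagonal."""

    values: np.ndarray
    labels: Sequence[str]
    method: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError(f"distance matrix must be {n}x{n}, got {d.shape}")
        if np.isnan(d).any():
            raise ValueError("distance matrix contains NaN")
        if not np.allclose(d, d.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal must be zero")
        if (d < -1e-9).any():
            raise ValueError("distances must be non-negative")
        self.values = np.clip(d, 0.0, None)


@dataclass
class DendrogramNode:
    """Node of a rooted binary merge tree; leaves carry a label, height 0."""

    height: float
    label: str | None = None
    children: tuple["DendrogramNode", "DendrogramNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        return self.children[0].leaves() + self.children[1].leaves()


@dataclass
class Dendrogram:
    """UPGMA tree over residues with ultrametric merge heights."""

    root: DendrogramNode
    merge_heights: list[float] = field(default_factory=list)

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def to_newick(self) -> str:
        """Newick string; branch length = parent height - child height."""

        def rec(node: DendrogramNode, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{bl:.6g}"
            inner = ",".join(rec(c, node.height) for c in node.children)
            return f"({inner}):{bl:.6g}"

        if self.root.is_leaf:
            return f"{self.root.label};"
        inner = ",".join(rec(c, self.root.height) for c in self.root.children)
        return f"({inner});"

    def cophenetic(self) -> DistanceMatrix:
        """Cophenetic distances: twice the height of the lowest common ancestor."""
        labels = sorted(self.leaves())
        idx = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        d = np.zeros((n, n))

        def rec(node: DendrogramNode) -> list[str]:
            if node.is_leaf:
                return [node.label]  # type: ignore[list-item]
            left = rec(node.children[0])
            right = rec(node.children[1])
            for a in left:
                for b in right:
                    d[idx[a], idx[b]] = d[idx[b], idx[a]] = 2.0 * node.height
            return left + right

        rec(self.root)
        return DistanceMatrix(values=d, labels=labels, method="cophenetic")


@dataclass
class Projection:
    """Classical-MDS coordinates for the residues plus the eigenvalue spectrum."""

    coordinates: np.ndarray  # (n, k)
    labels: Sequence[str]
    eigenvalues: np.ndarray  # full spectrum, non-increasing
    truncated: bool = False  # True when k exceeded the positive-eigenvalue count


def difference_matrix(
    a: SubstitutionMatrix, b: SubstitutionMatrix
) -> DifferenceMatrix:
    """Cell-wise a - b on the integer scores; alphabets must match."""
    if a.alphabet != b.alphabet:
        raise ValueError(
            f"matrix alphabets differ: {a.alphabet!r} vs {b.alphabet!r}"
        )
    la = a.provenance.get("label", "A")
    lb = b.provenance.get("label", "B")
    return DifferenceMatrix(
        values=a.scores_int - b.scores_int,
        label_a=la,
        label_b=lb,
        alphabet=a.alphabet,
    )


def score_to_distance(
    m: SubstitutionMatrix, method: str = "diagonal_deficit", integer: bool = True
) -> DistanceMatrix:
    """Turn a scoring matrix into residue dissimilarities.

    ``diagonal_deficit``: d_ij = S_ii + S_jj - 2 S_ij, floored at 0.
    ``correlation``: d_ij = 1 - Pearson correlation of matrix rows i and j
    (raises on constant rows, whose correlation is undefined).
    """
    S = (m.scores_int if integer else m.scores_real).astype(float)
    labels = list(m.alphabet)
    if method == "diagonal_deficit":
        diag = np.diag(S)
        d = diag[:, None] + diag[None, :] - 2.0 * S
        np.fill_diagonal(d, 0.0)
        d = np.clip(d, 0.0, None)
    elif method == "correlation":
        sd = S.std(axis=1)
        if (sd == 0).any():
            bad = labels[int(np.argmax(sd == 0))]
            raise ValueError(f"row {bad!r} is constant; correlation undefined")
        d = 1.0 - np.corrcoef(S)
        np.fill_diagonal(d, 0.0)
        d = np.clip(d, 0.0, None)
    else:
        raise ValueError(f"unknown score-to-distance method {method!r}")
    return DistanceMatrix(values=d, labels=labels, method=method)


def upgma(d: DistanceMatrix) -> Dendrogram:
    """Unweighted pair-group (arithmetic mean) agglomerative clustering.

    Cluster-to-cluster distance is the unweighted mean over member pairs;
    each merge sits at half the merged distance, so the tree is ultrametric.
    Ties are broken by the lexicographically smallest pair of cluster labels
    (a cluster is labelled by its smallest member), giving deterministic
    output.
    """
    labels = list(d.labels)
    n = len(labels)
    if n == 0:
        raise ValueError("empty distance matrix")
    dist = d.values.copy()
    clusters: dict[int, DendrogramNode] = {
        i: DendrogramNode(height=0.0, label=labels[i]) for i in range(n)
    }
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    minlab: dict[int, str] = {i: labels[i] for i in range(n)}
    # inter-cluster mean distances, keyed on frozenset pairs
    cd = {
        (i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    heights: list[float] = []
    next_id = n
    active = set(range(n))
    while len(active) > 1:
        # closest pair; ties -> lexicographically smallest (minlab_i, minlab_j)
        best = None
        for (i, j), v in cd.items():
            key = tuple(sorted((minlab[i], minlab[j])))
            cand = (v, key, (i, j))
            if best is None or cand[:2] < best[:2]:
                best = cand
        dij, _, (i, j) = best
        h = dij / 2.0
        heights.append(h)
        ni, nj = len(members[i]), len(members[j])
        node = DendrogramNode(
            height=h,
            children=tuple(
                sorted((clusters[i], clusters[j]), key=lambda c: min(c.leaves()))
            ),
        )
        new = next_id
        next_id += 1
        members[new] = members[i] + members[j]
        minlab[new] = min(minlab[i], minlab[j])
        clusters[new] = node
        active -= {i, j}
        for k in list(active):
            a = cd.pop((min(i, k), max(i, k)))
            b = cd.pop((min(j, k), max(j, k)))
            nk = len(members[k])
            # unweighted mean over all member pairs of (i u j) x k
            cd[(min(new, k), max(new, k))] = (ni * a + nj * b) / (ni + nj)
            del nk
        cd.pop((i, j), None)
        active.add(new)
        for key in (i, j):
            clusters.pop(key)
            members.pop(key)
            minlab.pop(key)
    root = clusters[active.pop()]
    return Dendrogram(root=root, merge_heights=heights)


def classical_mds(d: DistanceMatrix, k: int = 2) -> Projection:
    """Torgerson scaling: double-centre -d^2/2, eigendecompose, take top k.

    Coordinates are centred at the origin and ordered by decreasing
    eigenvalue.  Axis signs are fixed by making each axis's
    largest-magnitude coordinate positive, so output is fully deterministic.
    If fewer than ``k`` eigenvalues are positive the embedding is truncated
    and flagged.
    """
    D = d.values
    n = D.shape[0]
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    B = (B + B.T) / 2.0
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    pos = w > max(1e-12, 1e-9 * abs(w[0])) if n else w > 0
    n_pos = int(pos.sum())
    k_eff = min(k, n_pos)
    coords = V[:, :k_eff] * np.sqrt(w[:k_eff])
    for axis in range(k_eff):
        j = int(np.argmax(np.abs(coords[:, axis])))
        if coords[j, axis] < 0:
            coords[:, axis] = -coords[:, axis]
    coords = coords - coords.mean(axis=0)
    return Projection(
        coordinates=coords,
        labels=list(d.labels),
        eigenvalues=w,
        truncated=k_eff < k,
    )
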