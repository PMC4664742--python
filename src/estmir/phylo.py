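"""Distance-based phylogeny of miRNA sequences.

Mature (or precursor) sequences are compared by p-distance — the
fraction of differing sites over the pairwise-alignable columns of a
global alignment (match 1, mismatch -1, gap -2) — and the distance
matrix is clustered with the canonical Saitou-Nei neighbor-joining
algorithm.  The result is an unrooted tree with branch lengths,
serialized as Newick.  NJ is consistent: on an additive distance matrix
it recovers the generating tree exactly, which is what the test suite
exploits.

Tie-breaking is deterministic (smallest active-node index pair), and
negative branch-length estimates are clamped to zero with the deficit
moved to the sibling branch so path lengths are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import Align

from .seqio import SequenceRecord


@dataclass
class TreeNode:
    """A node of an (un)rooted tree; children carry branch lengths."""

    name: str = ""
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric p-distance matrix over an ordered taxon list."""

    taxa: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxon count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def pairwise_pdistance(a: str, b: str) -> float:
    """p-distance over the non-gap columns of a global alignment.

    Scoring: match 1, mismatch -1, gap -2.  Columns where either
    sequence is gapped are excluded from the denominator; if no column
    aligns residues (degenerate), the distance is 1.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a, b = a.upper().replace("T", "U"), b.upper().replace("T", "U")
    if a == b:
        return 0.0
    aln = _aligner().align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    diffs = comparable = 0
    for x, y in zip(sa, sb):
        if x == "-" or y == "-":
            continue
        comparable += 1
        if x != y:
            diffs += 1
    if comparable == 0:
        return 1.0
    return diffs / comparable


def distance_matrix(records: Sequence[SequenceRecord]) -> DistanceMatrix:
    """All-pairs p-distance matrix of a sequence collection."""
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_pdistance(
                records[i].sequence, records[j].sequence
            )
    return DistanceMatrix(taxa=tuple(r.id for r in records), d=d)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted tree.

    The returned :class:`TreeNode` is the final trifurcating junction
    (for >= 4 taxa) or the single 3-way junction (3 taxa).  Ties in the
    Q criterion break toward the smallest active-index pair; negative
    branch estimates are clamped to zero with the deficit shifted onto
    the sibling branch.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return li, max(lj, 0.0)

    while len(active) > 3:
        r = len(active)
        # row sums over active set
        R = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * d[i, j] - R[i] - R[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        li = d[i, j] / 2 + (R[i] - R[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        li, lj = clamp(li, lj)
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # new node reuses slot i; distances by the NJ reduction formula
        for k in active:
            if k in (i, j):
                continue
            d[i, k] = d[k, i] = (d[i, k] + d[j, k] - d[i, j]) / 2
        nodes[i] = parent
        active.remove(j)

    i, j, k = active
    # three-point formulas for the final junction
    li = (d[i, j] + d[i, k] - d[j, k]) / 2
    lj = (d[i, j] + d[j, k] - d[i, k]) / 2
    lk = (d[i, k] + d[j, k] - d[i, j]) / 2
    root = TreeNode(
        children=[
            (nodes[i], max(li, 0.0)),
            (nodes[j], max(lj, 0.0)),
            (nodes[k], max(lk, 0.0)),
        ]
    )
    return root


def to_newick(tree: TreeNode, precision: int = 10) -> str:
    """Serialize a tree as Newick with branch lengths, no internal labels."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return node.name
        parts = [
            f"{render(child)}:{length:.{precision}g}"
            for child, length in node.children
        ]
        return "(" + ",".join(parts) + ")"

    return render(tree) + ";"


def write_newick(tree: TreeNode, path: str | Path) -> None:
    Path(path).write_text(to_newick(tree) + "\n")


def write_phylip(dm: DistanceMatrix, path: str | Path) -> None:
    """Square PHYLIP distance-matrix output."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.taxa)}\n")
        for i, taxon in enumerate(dm.taxa):
            row = " ".join(f"{x:.6f}" for x in dm.d[i])
            fh.write(f"{taxon}  {row}\n")
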