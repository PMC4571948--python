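"""Neighbor-joining phylogeny of AR-containing zDHHC enzymes.

Distances between protein sequences are ``1 − fractional identity`` computed
from the pairwise global alignment (columns with a gap in either row count
against identity; gap–gap columns cannot occur in a pairwise alignment).
Tree construction is the Saitou–Nei neighbor-joining algorithm: repeatedly
join the pair minimizing the Q criterion, assign branch lengths, reduce the
matrix, and finish with an unrooted trifurcation over the last three nodes.
Ties in the Q criterion are broken by the lowest index pair. Negative branch
lengths are reported as computed, with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .align import nw_align
from .scan import ProteinRecord

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """A symmetric, zero-diagonal, finite, non-negative distance matrix."""

    taxa: list
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa count")
        if len(set(self.taxa)) != n:
            raise ValueError("taxa labels must be unique")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")

    def __len__(self) -> int:
        return len(self.taxa)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# armotif distance matrix v1 (1 - fractional identity)\n")
            fh.write("taxon\t" + "\t".join(self.taxa) + "\n")
            for label, row in zip(self.taxa, self.d):
                fh.write(label + "\t" + "\t".join(f"{x:.6g}" for x in row) + "\n")


def identity_distance(a: str, b: str, **align_kwargs) -> float:
    """``1 − identical columns / alignment columns`` from the global alignment."""
    res = nw_align(a, b, **align_kwargs)
    cols = [
        (x, y)
        for x, y in zip(res.aligned_a, res.aligned_b)
        if not (x == "-" and y == "-")
    ]
    identical = sum(x == y and x != "-" for x, y in cols)
    return 1.0 - identical / len(cols)


def distance_matrix_from_records(
    records: Sequence[ProteinRecord], **align_kwargs
) -> DistanceMatrix:
    """All-pairs identity distances among records."""
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = identity_distance(
                records[i].sequence, records[j].sequence, **align_kwargs
            )
    return DistanceMatrix(taxa=[r.id for r in records], d=d)


# --- trees -------------------------------------------------------------------

@dataclass
class TreeNode:
    label: Optional[str] = None
    children: list = field(default_factory=list)  # (TreeNode, branch_length)

    def is_leaf(self) -> bool:
        return not self.children

    def newick_fragment(self) -> str:
        if self.is_leaf():
            return self.label or ""
        inner = ",".join(
            f"{child.newick_fragment()}:{length:.6g}"
            for child, length in self.children
        )
        return f"({inner})" + (self.label or "")


@dataclass
class PhyloTree:
    """An unrooted tree represented from an arbitrary internal trifurcation."""

    root: TreeNode

    def newick(self) -> str:
        return self.root.newick_fragment() + ";"

    def leaf_labels(self) -> list:
        out = []

        def walk(node):
            if node.is_leaf():
                out.append(node.label)
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return out

    def total_length(self) -> float:
        total = 0.0

        def walk(node):
            nonlocal total
            for child, length in node.children:
                total += length
                walk(child)

        walk(self.root)
        return total


def nj(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    Requires at least 3 taxa. At each step the pair (i, j) minimizing
    ``Q(i,j) = (N-2) d(i,j) − r_i − r_j`` is joined (ties: lowest index
    pair); branch lengths follow the standard formulas, and the last three
    nodes are joined in an unrooted trifurcation.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    d = dm.d.copy()
    nodes: List[TreeNode] = [TreeNode(label=t) for t in dm.taxa]
    negative = False

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        best_q = np.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0 or lj < 0:
            negative = True
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        new_dist = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.zeros((len(keep) + 1, len(keep) + 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = new_dist[keep]
        d_new[:-1, -1] = new_dist[keep]
        d = d_new
        nodes = [nodes[k] for k in keep] + [parent]

    # unrooted trifurcation over the final three nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    if min(la, lb, lc) < 0:
        negative = True
    root = TreeNode(children=[(nodes[0], la), (nodes[1], lb), (nodes[2], lc)])
    if negative:
        logger.warning("neighbor joining produced negative branch length(s)")
    return PhyloTree(root=root)


def nj_from_records(records: Sequence[ProteinRecord], **align_kwargs) -> PhyloTree:
    """Convenience: identity distances then NJ."""
    return nj(distance_matrix_from_records(records, **align_kwargs))
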