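"""Distance matrices and neighbour-joining phylogeny with bootstrap support.

The distance model mirrors the classical MEGA-style settings: amino-acid
"number of differences" (or p-distance) with complete deletion, i.e. every
alignment column containing at least one gap is removed before counting.
Neighbour joining uses the standard Q-criterion agglomeration with a
deterministic lowest-index tie-break; negative branch lengths are clamped
to zero with the deficit moved to the sibling edge so displayed trees stay
non-negative.  Bootstrap resamples alignment columns with replacement and
re-applies the deletion policy per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .sequence_io import GAP, Alignment


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    method: str = "count_differences"  # {"count_differences", "p_distance"}
    deletion_policy: str = "complete"  # {"complete", "pairwise"}

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(m < 0):
            raise ValueError("distances must be non-negative")
        self.matrix = m

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class TreeNode:
    """Node of an (un)rooted tree; leaves carry labels, edges carry lengths."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None  # bootstrap %, internal edges only

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

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]


@dataclass
class PhyloTree:
    """Unrooted tree represented by an arbitrary internal root node."""

    root: TreeNode
    ids: list[str]

    def leaf_labels(self) -> list[str]:
        return self.root.leaf_labels()

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each named by its smaller/canonical leaf set."""
        all_leaves = frozenset(self.leaf_labels())
        splits: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.label])
            below = frozenset().union(*(walk(c) for c, _ in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                splits.add(_canonical_split(below, all_leaves))
            return below

        for child, _ in self.root.children:
            walk(child)
        return splits


def _canonical_split(side: frozenset[str], universe: frozenset[str]) -> frozenset[str]:
    other = universe - side
    return min(side, other, key=lambda s: (len(s), sorted(s)))


def distance_matrix(
    aln: Alignment,
    method: str = "count_differences",
    deletion_policy: str = "complete",
) -> DistanceMatrix:
    """Pairwise distances from an alignment under the chosen deletion policy.

    Complete deletion drops every column with a gap in any row, so all pairs
    are computed over the same column set; pairwise deletion drops columns
    per pair.  ``count_differences`` counts differing retained columns;
    ``p_distance`` divides by the number of retained columns.
    """
    if len(aln) < 2:
        raise ValueError("need at least two rows")
    rows = np.array([list(r) for r in aln.rows])
    n = len(aln)
    if deletion_policy == "complete":
        keep = ~np.any(rows == GAP, axis=0)
        if not keep.any():
            raise ValueError(
                "complete deletion removed every column; no shared gap-free "
                "region across the alignment"
            )
        rows = rows[:, keep]
        ncols = rows.shape[1]
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                diff = int(np.sum(rows[i] != rows[j]))
                d = diff if method == "count_differences" else diff / ncols
                mat[i, j] = mat[j, i] = d
    elif deletion_policy == "pairwise":
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                keep = (rows[i] != GAP) & (rows[j] != GAP)
                kept = int(keep.sum())
                if kept == 0:
                    raise ValueError(f"no shared columns for pair ({aln.ids[i]}, {aln.ids[j]})")
                diff = int(np.sum(rows[i, keep] != rows[j, keep]))
                mat[i, j] = mat[j, i] = diff if method == "count_differences" else diff / kept
    else:
        raise ValueError(f"unknown deletion policy {deletion_policy!r}")
    return DistanceMatrix(list(aln.ids), mat, method, deletion_policy)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbour joining with deterministic tie-breaking.

    Pairs minimising the Q-criterion are joined; ties resolve to the lowest
    index pair.  On additive distance matrices the generating topology and
    branch lengths are recovered exactly.  Negative branch estimates are
    clamped to zero and the deficit added to the sibling branch.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbour joining requires at least 3 taxa")
    D = dm.matrix.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(label=i) for i in dm.ids]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        # Q[i,j] = (m-2) d(i,j) - r_i - r_j
        Q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(Q, np.inf)
        best = np.unravel_index(np.argmin(Q), Q.shape)  # first minimum: lowest index pair
        ai, aj = sorted((int(best[0]), int(best[1])))
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (totals[ai] - totals[aj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node u to every other active node k
        newdist = np.zeros(D.shape[0])
        for k in active:
            if k in (i, j):
                continue
            newdist[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        u = D.shape[0] - 1
        D[u, :-1] = newdist
        D[:-1, u] = newdist
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    # three-taxon closed form
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    li, lj, lk = (max(x, 0.0) for x in (li, lj, lk))
    root = TreeNode(children=[(nodes[i], li), (nodes[j], lj), (nodes[k], lk)])
    return PhyloTree(root=root, ids=list(dm.ids))


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def bootstrap_support(
    aln: Alignment,
    method: str = "count_differences",
    deletion_policy: str = "complete",
    replicates: int = 1000,
    seed: int = 0,
) -> PhyloTree:
    """NJ tree with bootstrap supports on internal edges.

    Columns of the original alignment are resampled with replacement per
    replicate; the deletion policy is re-applied to each resampled
    alignment before distances are computed.  Support of an internal edge
    is the percentage of replicates whose tree contains the same
    bipartition.  Fully reproducible under a fixed seed.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    tree = neighbor_joining(distance_matrix(aln, method, deletion_policy))
    target_splits = {s: 0 for s in tree.bipartitions()}
    rng = np.random.default_rng(seed)
    ncol = aln.length
    rows = np.array([list(r) for r in aln.rows])
    done = 0
    for _ in range(replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep = Alignment(list(aln.ids), ["".join(row) for row in rows[:, cols]])
        try:
            rep_tree = neighbor_joining(distance_matrix(rep, method, deletion_policy))
        except ValueError:
            continue  # replicate lost all gap-free columns; skipped
        done += 1
        rep_splits = rep_tree.bipartitions()
        for s in target_splits:
            if s in rep_splits:
                target_splits[s] += 1
    if done == 0:
        raise ValueError("every bootstrap replicate was degenerate")
    _annotate_supports(tree, {s: 100.0 * c / done for s, c in target_splits.items()})
    return tree


def _annotate_supports(tree: PhyloTree, supports: dict[frozenset[str], float]) -> None:
    universe = frozenset(tree.leaf_labels())

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.label])
        below = frozenset().union(*(walk(c) for c, _ in node.children))
        if 1 < len(below) < len(universe) - 1:
            node.support = supports.get(_canonical_split(below, universe))
        return below

    for child, _ in tree.root.children:
        walk(child)


def to_newick(tree: PhyloTree, include_support: bool = True) -> str:
    """Serialise to newick; bootstrap supports become internal node labels."""

    def fmt(node: TreeNode, length: float | None) -> str:
        if node.is_leaf:
            body = node.label
        else:
            inner = ",".join(fmt(c, l) for c, l in node.children)
            label = ""
            if include_support and node.support is not None:
                label = _fmt_num(node.support)
            body = f"({inner}){label}"
        if length is None:
            return body
        return f"{body}:{_fmt_num(length)}"

    inner = ",".join(fmt(c, l) for c, l in tree.root.children)
    return f"({inner});"


def _fmt_num(x: float) -> str:
    if x == int(x):
        return str(int(x))
    return f"{x:.10g}"


def write_distance_tsv(dm: DistanceMatrix, path) -> None:
    import pandas as pd

    pd.DataFrame(dm.matrix, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")
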