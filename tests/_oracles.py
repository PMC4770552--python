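"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route independent of the
implementation it checks: exhaustive enumeration for alignment scores and
hypergeometric tails, simulate-then-recover trees for neighbour joining,
raw base-set logic for degenerate primer matching.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

from nirktools.reference_mapping import Scoring
from nirktools.sequence_io import IUPAC_SETS


def brute_force_align_score(a: str, b: str, scoring: Scoring) -> float:
    """Max score over ALL global alignments, by explicit path enumeration."""
    go, ge = scoring.gap_open, scoring.gap_extend
    best = -math.inf

    def rec(i: int, j: int, prev: str, score: float) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + scoring.substitution(a[i], b[j]))
        if i < len(a):
            rec(i + 1, j, "X", score - (ge if prev == "X" else go))
        if j < len(b):
            rec(i, j + 1, "Y", score - (ge if prev == "Y" else go))

    rec(0, 0, "", 0.0)
    return best


def exact_hypergeom_tails(n: int, n1: int, n2: int, j_obs: int) -> tuple[Fraction, Fraction]:
    """(p_lt, p_gt) by exact rational enumeration of P(j)=C(n1,j)C(n-n1,n2-j)/C(n,n2)."""
    denom = math.comb(n, n2)
    pmf = {
        j: Fraction(math.comb(n1, j) * math.comb(n - n1, n2 - j), denom)
        for j in range(max(0, n1 + n2 - n), min(n1, n2) + 1)
    }
    p_lt = sum((p for j, p in pmf.items() if j <= j_obs), Fraction(0))
    p_gt = sum((p for j, p in pmf.items() if j >= j_obs), Fraction(0))
    return p_lt, p_gt


class _ONode:
    __slots__ = ("label", "children")

    def __init__(self, label=None, children=()):
        self.label = label
        self.children = list(children)  # (child, branch length)


def random_additive_tree(rng: np.random.Generator, n: int):
    """Random unrooted binary tree -> (ids, additive distance matrix, splits).

    Built by random sequential joins with internal branch lengths >= 0.2
    (so the topology is identifiable) and leaf branches >= 0.05.
    """
    def edge() -> float:
        return 0.2 + float(rng.random())

    ids = [f"t{k}" for k in range(n)]
    nodes = [_ONode(label=i) for i in ids]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        new = _ONode(children=[(nodes[i], edge()), (nodes[j], edge())])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)]
        nodes.append(new)
    root = _ONode(children=[(nd, edge()) for nd in nodes])
    # leaf distances by DFS
    dists = {}

    def leaves_below(node, acc):
        if node.label is not None and not node.children:
            return {node.label: acc}
        out = {}
        for child, ln in node.children:
            out.update(leaves_below(child, acc + ln))
        return out

    def collect(node):
        if not node.children:
            return
        sides = [leaves_below(c, ln) for c, ln in node.children]
        for si in range(len(sides)):
            for sj in range(si + 1, len(sides)):
                for la, da in sides[si].items():
                    for lb, db in sides[sj].items():
                        dists[frozenset((la, lb))] = da + db
        for child, _ in node.children:
            collect(child)

    collect(root)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dists[frozenset((ids[i], ids[j]))]

    splits = set()
    universe = frozenset(ids)

    def split_walk(node):
        if not node.children:
            return frozenset([node.label])
        below = frozenset().union(*(split_walk(c) for c, _ in node.children))
        if 1 < len(below) < n - 1:
            other = universe - below
            splits.add(min(below, other, key=lambda s: (len(s), sorted(s))))
        return below

    for child, _ in root.children:
        split_walk(child)
    return ids, D, splits


def tree_path_distances(tree) -> dict[frozenset, float]:
    """Leaf-to-leaf path lengths of a nirktools PhyloTree."""
    dists: dict[frozenset, float] = {}

    def leaves_below(node, acc):
        if node.is_leaf:
            return {node.label: acc}
        out = {}
        for child, ln in node.children:
            out.update(leaves_below(child, acc + ln))
        return out

    def collect(node):
        if node.is_leaf:
            return
        sides = [leaves_below(c, ln) for c, ln in node.children]
        for si in range(len(sides)):
            for sj in range(si + 1, len(sides)):
                for la, da in sides[si].items():
                    for lb, db in sides[sj].items():
                        dists[frozenset((la, lb))] = da + db
        for child, _ in node.children:
            collect(child)

    collect(tree.root)
    return dists


def best_site_oracle(primer_seq: str, template: str) -> tuple[int, int]:
    """(leftmost best 0-based offset, mismatch count) by raw base-set scan."""
    L = len(primer_seq)
    best_off, best_mm = 0, L + 1
    for off in range(len(template) - L + 1):
        mm = sum(
            1
            for p, t in zip(primer_seq, template[off : off + L])
            if not (IUPAC_SETS[p] & IUPAC_SETS[t])
        )
        if mm < best_mm:
            best_off, best_mm = off, mm
    return best_off, best_mm
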