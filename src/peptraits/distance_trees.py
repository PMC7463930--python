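"""Neighbor-joining trees on ACC distances, bootstrap support, and IC/TC.

Peptides are too short and too divergent for alignment-based phylogenetics, so
relatedness is summarised by Euclidean distances between standardized 36-term
ACC vectors, from which a classical Saitou–Nei neighbor-joining (NJ) tree is
built. Support comes from resampling the 36 descriptor dimensions (the
"characters") with replacement: each bootstrap replicate yields a new distance
matrix and NJ tree. Each internal bipartition of the main tree is then scored
by internode certainty,

    IC = 1 + p1*log2(p1) + p2*log2(p2),

where p1, p2 renormalize the bootstrap frequency f1 of the bipartition and the
frequency f2 of its most prevalent conflicting bipartition (p1 = f1/(f1+f2));
IC is 1 when no conflicting bipartition is observed, 0 under maximal conflict.
Tree certainty TC is the sum of IC over the n−3 internal edges.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode


def euclidean_distances(X: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Euclidean distances between descriptor rows."""
    if len(X) < 3:
        raise ValueError("need at least 3 peptides for a distance tree")
    if X.index.has_duplicates:
        raise ValueError("duplicate peptide ids in descriptor table")
    from scipy.spatial.distance import pdist, squareform

    # pdist works on row differences, so identical rows are at exactly 0
    d = squareform(pdist(X.to_numpy(dtype=float), metric="euclidean"))
    return DistanceMatrix(d, ids=[str(i) for i in X.index])


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Classical Saitou–Nei NJ; exact on additive distances.

    Joins minimise the Q criterion; ties break toward the smallest index pair
    so runs are deterministic. Negative branch lengths are clamped to zero
    with the deficit moved to the sibling edge, preserving the path length
    through the join. Returns an unrooted tree as a trifurcating-root
    :class:`skbio.TreeNode` for n >= 3 leaves.
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    d = dm.data.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=name) for name in ids]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = float(li)
        nodes[j].length = float(lj)
        dnew = (d[i] + d[j] - d[i, j]) / 2
        keep = [x for x in range(m) if x not in (i, j)]
        d = np.vstack([d[keep][:, keep], dnew[keep]])
        d = np.hstack([d, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[x] for x in keep] + [parent]

    a, b, c = nodes
    da, db, dc = d[0, 1], d[0, 2], d[1, 2]
    la = (da + db - dc) / 2
    lb = (da + dc - db) / 2
    lc = (db + dc - da) / 2
    root = TreeNode(children=[a, b, c])
    a.length, b.length, c.length = (max(0.0, float(x)) for x in (la, lb, lc))
    return root


def bipartitions(tree: TreeNode) -> list[frozenset[str]]:
    """Canonical internal bipartitions (splits) of an unrooted tree.

    Each internal edge separates the leaves into two sides; the split is
    represented by the side containing the lexicographically smallest leaf.
    Trivial splits (single leaf / all leaves) are excluded, and duplicates are
    collapsed (a rooted-binary encoding of an unrooted tree yields the same
    split from both children of the root).
    """
    leaves = frozenset(l.name for l in tree.tips())
    anchor = min(leaves)
    splits: dict[frozenset[str], None] = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(l.name for l in node.tips())
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        if anchor not in side:
            side = leaves - side
        splits[side] = None
    return list(splits)


def _conflicts(a: frozenset, b: frozenset, leaves: frozenset) -> bool:
    """Two splits conflict when no side of one nests inside a side of the other."""
    ac, bc = leaves - a, leaves - b
    return all(x & y for x, y in ((a, b), (a, bc), (ac, b), (ac, bc)))


def bootstrap_trees(
    X: pd.DataFrame, B: int = 1000, seed: int = 0
) -> list[TreeNode]:
    """NJ trees from ``B`` replicates resampling descriptor columns with replacement."""
    if B < 1:
        raise ValueError("need at least one bootstrap replicate")
    rng = np.random.default_rng(seed)
    ncol = X.shape[1]
    trees = []
    for _ in range(B):
        cols = rng.integers(0, ncol, size=ncol)
        Xb = pd.DataFrame(X.to_numpy()[:, cols], index=X.index)
        trees.append(neighbor_joining(euclidean_distances(Xb)))
    return trees


@dataclass(frozen=True)
class SplitSupport:
    split: frozenset[str]
    f1: float  # bootstrap frequency of the split
    f2: float  # frequency of its most prevalent conflicting split
    ic: float


def internode_certainty(
    main: TreeNode, boots: list[TreeNode]
) -> tuple[list[SplitSupport], float]:
    """IC per internal edge of the main tree and the total tree certainty TC."""
    leaves = frozenset(l.name for l in main.tips())
    for t in boots:
        if frozenset(l.name for l in t.tips()) != leaves:
            raise ValueError("bootstrap tree leaf set differs from main tree")
    counts: dict[frozenset, int] = {}
    for t in boots:
        for s in bipartitions(t):
            counts[s] = counts.get(s, 0) + 1
    B = len(boots)
    supports = []
    tc = 0.0
    for split in bipartitions(main):
        f1 = counts.get(split, 0) / B
        f2 = max(
            (c / B for s, c in counts.items() if s != split and _conflicts(split, s, leaves)),
            default=0.0,
        )
        if f2 == 0.0:
            ic = 1.0
        else:
            p1, p2 = f1 / (f1 + f2), f2 / (f1 + f2)
            ic = 1.0
            for p in (p1, p2):
                if p > 0:
                    ic += p * np.log2(p)
        supports.append(SplitSupport(split, f1, f2, float(ic)))
        tc += ic
    return supports, float(tc)


def annotate_ic(tree: TreeNode, supports: list[SplitSupport]) -> TreeNode:
    """Label the internal nodes of a copy of ``tree`` with their IC values."""
    tree = tree.copy()
    leaves = frozenset(l.name for l in tree.tips())
    anchor = min(leaves)
    by_split = {s.split: s.ic for s in supports}
    for node in tree.non_tips(include_self=False):
        side = frozenset(l.name for l in node.tips())
        if anchor not in side:
            side = leaves - side
        if side in by_split:
            node.name = f"{by_split[side]:.4f}"
    return tree


def write_newick(tree: TreeNode, path) -> None:
    """Write a newick file (unquoted labels, branch lengths after colons)."""
    tree.write(str(path), format="newick")


def newick_string(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def splits_table(supports: list[SplitSupport]) -> pd.DataFrame:
    """Splits and support as a table; split rendered as comma-joined leaf ids."""
    return pd.DataFrame(
        {
            "split": [",".join(sorted(s.split)) for s in supports],
            "f1": [s.f1 for s in supports],
            "f2": [s.f2 for s in supports],
            "IC": [s.ic for s in supports],
        }
    )
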