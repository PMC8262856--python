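"""Neighbor-joining trees, nonparametric bootstrap and monophyly tests.

Trees are scikit-bio ``TreeNode`` objects; Newick round-trips go through
scikit-bio's reader/writer.  Internal-node ``name`` carries the integer
bootstrap support (0-100) after :func:`bootstrap_support`.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from skbio import TreeNode

from .align import Msa, p_distance_matrix

__all__ = [
    "nj_tree",
    "bootstrap_support",
    "bipartitions",
    "is_monophyletic",
]


def _check_matrix(dist: np.ndarray) -> None:
    dist = np.asarray(dist, float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dist), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    if dist.shape[0] < 3:
        raise ValueError("need at least 3 taxa")


def nj_tree(dist: np.ndarray, names: Sequence[str]) -> TreeNode:
    """Saitou–Nei neighbor joining.

    Q-matrix ties are broken by the smallest (i, j) index pair in the
    current working order; negative branch lengths are clamped to zero
    (the clamped deficit is recorded on the tree as
    ``tree.negative_length_deficit``).
    """
    dist = np.asarray(dist, float).copy()
    _check_matrix(dist)
    if len(names) != dist.shape[0]:
        raise ValueError("names do not match matrix size")

    nodes: list[TreeNode] = [TreeNode(name=n) for n in names]
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(nodes) > 3:
        n = len(nodes)
        r = dist.sum(axis=1)
        q = (n - 2) * dist - (r[:, None] + r[None, :])
        # smallest (i, j) pair on ties: triu_indices is row-major, so the
        # first occurrence of the minimum is the lexicographic smallest pair
        iu = np.triu_indices(n, 1)
        k = int(np.argmin(q[iu]))
        i, j = int(iu[0][k]), int(iu[1][k])
        li = dist[i, j] / 2 + (r[i] - r[j]) / (2 * (n - 2))
        lj = dist[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = clamp(li)
        child_j.length = clamp(lj)
        parent = TreeNode(children=[child_i, child_j])

        new_d = (dist[i, :] + dist[j, :] - dist[i, j]) / 2
        keep = [k for k in range(n) if k not in (i, j)]
        dist = np.vstack([dist[keep][:, keep], new_d[keep][None, :]])
        dist = np.hstack([dist, np.append(new_d[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # final three-point join
    d01, d02, d12 = dist[0, 1], dist[0, 2], dist[1, 2]
    lengths = [
        (d01 + d02 - d12) / 2,
        (d01 + d12 - d02) / 2,
        (d02 + d12 - d01) / 2,
    ]
    for node, length in zip(nodes, lengths):
        node.length = clamp(length)
    root = TreeNode(children=list(nodes))
    root.negative_length_deficit = deficit
    return root


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree.

    Each internal edge is represented canonically as the side that does
    not contain the lexicographically smallest tip.
    """
    tips = {t.name for t in tree.tips()}
    anchor = min(tips)
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        below = {t.name for t in node.tips()}
        side = below if anchor not in below else tips - below
        if 1 < len(side) < len(tips) - 1:
            parts.add(frozenset(side))
    return parts


def bootstrap_support(
    msa: Msa, replicates: int = 100, seed: int = 0
) -> TreeNode:
    """NJ tree from an alignment with column-bootstrap supports.

    Columns are resampled with replacement per replicate; the support of
    an internal edge is the percentage of replicate trees containing its
    bipartition.  Supports are stored as internal-node names (integers).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    tree = nj_tree(p_distance_matrix(msa), msa.names)
    counts: dict[frozenset[str], int] = {p: 0 for p in bipartitions(tree)}

    rng = np.random.default_rng(seed)
    ncols = msa.ncols
    for _ in range(replicates):
        cols = rng.integers(0, ncols, size=ncols)
        rows = ["".join(row[c] for c in cols) for row in msa.rows]
        rep_msa = Msa(names=msa.names, rows=rows)
        rep_tree = nj_tree(
            p_distance_matrix(rep_msa, on_zero_overlap="max"), msa.names
        )
        rep_parts = bipartitions(rep_tree)
        for part in counts:
            if part in rep_parts:
                counts[part] += 1

    tips = {t.name for t in tree.tips()}
    anchor = min(tips)
    for node in tree.non_tips(include_self=False):
        below = {t.name for t in node.tips()}
        side = frozenset(below if anchor not in below else tips - below)
        if side in counts:
            node.name = str(round(100 * counts[side] / replicates))
    return tree


def is_monophyletic(tree: TreeNode, tips: Iterable[str]) -> bool:
    """True iff some edge of the unrooted tree splits exactly ``tips``
    from all other tips."""
    query = set(tips)
    all_tips = {t.name for t in tree.tips()}
    unknown = query - all_tips
    if unknown:
        raise ValueError(f"unknown tips: {sorted(unknown)}")
    # trivial splits: single tips and their complements are always edges
    if len(query) in (1, len(all_tips) - 1, len(all_tips)):
        return True
    anchor = min(all_tips)
    canonical = frozenset(query if anchor not in query else all_tips - query)
    return canonical in bipartitions(tree)
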