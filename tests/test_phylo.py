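import itertools
import zlib

import numpy as np
import pytest

from hipsurvey.align import Msa, p_distance_matrix
from hipsurvey.phylo import bipartitions, bootstrap_support, is_monophyletic, nj_tree
from hipsurvey.synth import make_family_template, mutate


# ---------------------------------------------------------------------------
# independent unrooted-tree machinery for oracle construction
# ---------------------------------------------------------------------------

def _all_unrooted_topologies(taxa):
    """All unrooted binary topologies as adjacency dicts (tip-insertion)."""
    assert len(taxa) >= 3
    first = {"i0": set(taxa[:3])}
    for t in taxa[:3]:
        first[t] = {"i0"}
    trees = [first]
    next_internal = 1
    for tip in taxa[3:]:
        grown = []
        for tree in trees:
            edges = {
                tuple(sorted((u, v))) for u, nbrs in tree.items() for v in nbrs
            }
            for u, v in edges:
                new = {k: set(vs) for k, vs in tree.items()}
                w = f"i{next_internal}"
                new[u].discard(v)
                new[v].discard(u)
                new[u].add(w)
                new[v].add(w)
                new[w] = {u, v, tip}
                new[tip] = {w}
                grown.append(new)
        next_internal += 1
        trees = grown
    return trees


def _tree_distances(adj, taxa, rng):
    """Random positive branch lengths; additive path-length matrix."""
    lengths = {
        tuple(sorted((u, v))): float(rng.uniform(0.1, 1.0))
        for u, nbrs in adj.items()
        for v in nbrs
    }

    def dist_from(src):
        out = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nbr in adj[node]:
                if nbr not in out:
                    out[nbr] = out[node] + lengths[tuple(sorted((node, nbr)))]
                    stack.append(nbr)
        return out

    n = len(taxa)
    d = np.zeros((n, n))
    for i, a in enumerate(taxa):
        da = dist_from(a)
        for j, b in enumerate(taxa):
            d[i, j] = da[b]
    np.fill_diagonal(d, 0.0)
    return d


def _adj_bipartitions(adj, taxa):
    """Non-trivial bipartitions of an adjacency tree, canonicalized the
    same way as hipsurvey.phylo.bipartitions."""
    anchor = min(taxa)
    parts = set()
    internal = [k for k in adj if k.startswith("i")]
    for u, v in itertools.combinations(internal, 2):
        if v not in adj[u]:
            continue
        # tips reachable from v without crossing edge (u, v)
        seen = {u, v}
        stack = [v]
        side = set()
        while stack:
            node = stack.pop()
            for nbr in adj[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    if nbr.startswith("i"):
                        stack.append(nbr)
                    else:
                        side.add(nbr)
        if anchor in side:
            side = set(taxa) - side
        if 1 < len(side) < len(taxa) - 1:
            parts.add(frozenset(side))
    return parts


# ---------------------------------------------------------------------------


def test_nj_three_taxa_closed_form():
    d = np.array([[0.0, 5.0, 9.0], [5.0, 0.0, 10.0], [9.0, 10.0, 0.0]])
    tree = nj_tree(d, ["A", "B", "C"])
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths["A"] == pytest.approx((5 + 9 - 10) / 2)
    assert lengths["B"] == pytest.approx((5 + 10 - 9) / 2)
    assert lengths["C"] == pytest.approx((9 + 10 - 5) / 2)


def test_nj_recovers_all_topologies_exhaustively_small_n():
    rng = np.random.default_rng(17)
    for n in (4, 5):
        taxa = [chr(ord("A") + i) for i in range(n)]
        topologies = _all_unrooted_topologies(taxa)
        assert len(topologies) == {4: 3, 5: 15}[n]
        for adj in topologies:
            d = _tree_distances(adj, taxa, rng)
            tree = nj_tree(d, taxa)
            assert bipartitions(tree) == _adj_bipartitions(adj, taxa)


def test_nj_recovers_random_additive_topologies_up_to_n8():
    rng = np.random.default_rng(23)
    for n in (6, 7, 8):
        taxa = [f"t{i}" for i in range(n)]
        for _ in range(5):
            # random topology by random tip insertion
            adj = {"i0": set(taxa[:3])}
            for t in taxa[:3]:
                adj[t] = {"i0"}
            nxt = 1
            for tip in taxa[3:]:
                edges = [
                    tuple(sorted((u, v))) for u, nbrs in adj.items() for v in nbrs
                ]
                edges = sorted(set(edges))
                u, v = edges[int(rng.integers(len(edges)))]
                w = f"i{nxt}"
                nxt += 1
                adj[u].discard(v)
                adj[v].discard(u)
                adj[u].add(w)
                adj[v].add(w)
                adj[w] = {u, v, tip}
                adj[tip] = {w}
            d = _tree_distances(adj, taxa, rng)
            tree = nj_tree(d, taxa)
            assert bipartitions(tree) == _adj_bipartitions(adj, taxa)


def test_nj_agrees_with_skbio_reference():
    # cross-check the in-house NJ against scikit-bio's implementation
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(29)
    for trial in range(5):
        n = 6
        taxa = [f"t{i}" for i in range(n)]
        pts = rng.uniform(0, 1, size=(n, 4))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
        np.fill_diagonal(d, 0.0)
        ours = nj_tree(d, taxa)
        theirs = skbio_nj(DistanceMatrix(d, taxa))
        anchor = min(taxa)
        ref_parts = set()
        for node in theirs.non_tips(include_self=False):
            below = {t.name for t in node.tips()}
            side = below if anchor not in below else set(taxa) - below
            if 1 < len(side) < n - 1:
                ref_parts.add(frozenset(side))
        assert bipartitions(ours) == ref_parts


def test_nj_tie_break_deterministic():
    d = np.ones((4, 4)) - np.eye(4)
    taxa = ["A", "B", "C", "D"]
    t1 = nj_tree(d.copy(), taxa)
    t2 = nj_tree(d.copy(), taxa)
    assert str(t1) == str(t2)
    assert bipartitions(t1) == bipartitions(t2)


def test_nj_contract_errors():
    with pytest.raises(ValueError, match="symmetric"):
        nj_tree(np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0.0]]), list("ABC"))
    with pytest.raises(ValueError, match="diagonal"):
        nj_tree(np.array([[1, 1, 2], [1, 0, 1], [2, 1, 0.0]]), list("ABC"))
    with pytest.raises(ValueError, match="3 taxa"):
        nj_tree(np.zeros((2, 2)), list("AB"))
    with pytest.raises(ValueError, match="names"):
        nj_tree(np.zeros((3, 3)), list("AB"))


def test_nj_negative_length_clamped_and_recorded():
    # a non-additive matrix known to produce a negative NJ branch length
    d = np.array(
        [
            [0.0, 0.1, 0.4, 0.4],
            [0.1, 0.0, 0.4, 0.4],
            [0.4, 0.4, 0.0, 0.05],
            [0.4, 0.4, 0.05, 0.0],
        ]
    )
    tree = nj_tree(d, list("ABCD"))
    for node in tree.traverse(include_self=False):
        assert node.length >= 0
    assert tree.negative_length_deficit >= 0


def _four_family_msa(seed=31, members=4, divergence=0.1):
    rows, names = [], []
    for fam in ("HipA", "HipT", "HipG", "HipM"):
        template, _ = make_family_template(fam)
        template = template[:140]
        for k in range(members):
            names.append(f"{fam}_{k}")
            rows.append(
                mutate(template, divergence, seed + zlib.crc32(fam.encode()) % 1000 + k)
            )
    width = max(len(r) for r in rows)
    rows = [r.ljust(width, "-") for r in rows]
    return Msa(names=names, rows=rows)


def test_bootstrap_well_separated_families_full_support():
    msa = _four_family_msa()
    tree = bootstrap_support(msa, replicates=100, seed=5)
    fams = {"HipA", "HipT", "HipG", "HipM"}
    supports = {}
    anchor = min(msa.names)
    all_tips = set(msa.names)
    for node in tree.non_tips(include_self=False):
        below = {t.name for t in node.tips()}
        side = below if anchor not in below else all_tips - below
        prefixes = {name.split("_")[0] for name in side}
        if len(prefixes) == 1 and len(side) == 4:
            supports[prefixes.pop()] = int(node.name)
    for fam in fams:
        assert is_monophyletic(tree, [n for n in msa.names if n.startswith(fam)])
        if fam in supports:
            assert supports[fam] == 100
    # at least 3 of the 4 family edges are internal (one can abut the root)
    assert len(supports) >= 3


def test_bootstrap_single_replicate_support_binary():
    msa = _four_family_msa(members=2)
    tree = bootstrap_support(msa, replicates=1, seed=0)
    for node in tree.non_tips(include_self=False):
        if node.name is not None:
            assert int(node.name) in (0, 100)


def test_bootstrap_deterministic_under_seed():
    msa = _four_family_msa(members=2)
    t1 = bootstrap_support(msa, replicates=20, seed=77)
    t2 = bootstrap_support(msa, replicates=20, seed=77)
    assert str(t1) == str(t2)
    with pytest.raises(ValueError):
        bootstrap_support(msa, replicates=0)


def test_is_monophyletic_four_taxon_cases():
    d = np.array(
        [
            [0.0, 0.2, 0.9, 0.9],
            [0.2, 0.0, 0.9, 0.9],
            [0.9, 0.9, 0.0, 0.2],
            [0.9, 0.9, 0.2, 0.0],
        ]
    )
    tree = nj_tree(d, list("ABCD"))
    assert is_monophyletic(tree, ["A", "B"])
    assert is_monophyletic(tree, ["C", "D"])
    assert not is_monophyletic(tree, ["A", "C"])
    assert is_monophyletic(tree, ["A"])  # single tip
    assert is_monophyletic(tree, ["A", "B", "C", "D"])  # all tips
    assert is_monophyletic(tree, ["A", "B", "C"])  # complement of one tip
    with pytest.raises(ValueError, match="unknown"):
        is_monophyletic(tree, ["Z"])
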