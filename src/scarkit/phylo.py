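"""Neighbor-joining trees with bootstrap support.

The agglomeration is the classic Saitou-Nei algorithm on a distance
matrix (here usually K2P distances from the reference panel). Ties in the
Q criterion are broken deterministically by the lowest (i, j) pair in
input order, so a tree is a pure function of the matrix. Negative branch
lengths are kept internally (they preserve additivity checks) and only
clamped to zero on request when rendering.
"""

from __future__ import annotations

import io

import numpy as np
from skbio import TreeNode

from scarkit.distances import DistanceMatrix, distance_matrix_from_codes, encode_alignment
from scarkit.seqs import SpeciesPanel


class PhyloError(ValueError):
    pass


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree (unrooted, trifurcating root) from a distance matrix.

    For n taxa the result has 2n-3 edges. Deterministic: equal Q values
    are resolved in favour of the earliest (i, j) pair in input order.
    """
    n = len(dm.labels)
    if n < 3:
        raise PhyloError(f"neighbor-joining needs >=3 taxa, got {n}")
    if not np.all(np.isfinite(dm.d)):
        raise PhyloError("distance matrix contains NaN/inf")

    nodes: list[TreeNode] = [TreeNode(name=label) for label in dm.labels]
    D = {(i, j): float(dm.d[i, j]) for i in range(n) for j in range(n) if i != j}
    active = list(range(n))
    next_idx = n

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[(i, k)] for k in active if k != i) for i in active}
        best = None
        best_q = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (m - 2) * D[(i, j)] - r[i] - r[j]
                if best_q is None or q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = 0.5 * D[(i, j)] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[(i, j)] - li
        parent = TreeNode()
        ci, cj = nodes[i], nodes[j]
        ci.length, cj.length = li, lj
        parent.append(ci)
        parent.append(cj)
        nodes.append(parent)
        u = next_idx
        next_idx += 1
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (D[(i, k)] + D[(j, k)] - D[(i, j)])
            D[(u, k)] = D[(k, u)] = duk
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    root = TreeNode()
    la = 0.5 * (D[(a, b)] + D[(a, c)] - D[(b, c)])
    lb = 0.5 * (D[(a, b)] + D[(b, c)] - D[(a, c)])
    lc = 0.5 * (D[(a, c)] + D[(b, c)] - D[(a, b)])
    for k, lk in zip((a, b, c), (la, lb, lc)):
        nodes[k].length = lk
        root.append(nodes[k])
    return root


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, each keyed by the
    side not containing the lexicographically smallest leaf."""
    leaves = frozenset(t.name for t in tree.tips())
    anchor = min(leaves)
    bips: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        bips.add(frozenset(leaves - side) if anchor in side else side)
    return bips


def bootstrap_support(
    panel: SpeciesPanel,
    n_reps: int = 1000,
    seed: int = 0,
    model: str = "k2p",
) -> TreeNode:
    """NJ tree of the panel with bootstrap supports on internal nodes.

    Alignment columns are resampled with replacement ``n_reps`` times;
    the support of each internal bipartition of the reference tree is the
    percentage of replicate trees containing it. Deterministic given seed.
    """
    if n_reps < 1:
        raise PhyloError("n_reps must be >= 1")
    if len(panel.alignment) < 4:
        raise PhyloError("bootstrap needs >=4 sequences")
    codes = encode_alignment(panel.alignment)
    labels = [r.id for r in panel.alignment]
    ref_tree = nj_tree(distance_matrix_from_codes(codes, labels, model))
    counts: dict[frozenset[str], int] = {b: 0 for b in bipartitions(ref_tree)}
    rng = np.random.default_rng(seed)
    length = codes.shape[1]
    n_ok = 0
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        try:
            rep_dm = distance_matrix_from_codes(codes[:, cols], labels, model)
            rep_bips = bipartitions(nj_tree(rep_dm))
        except ValueError:
            continue  # saturated / incomparable replicate
        n_ok += 1
        for b in counts:
            if b in rep_bips:
                counts[b] += 1
    if n_ok == 0:
        raise PhyloError("all bootstrap replicates failed")
    for node in ref_tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        leaves = frozenset(t.name for t in ref_tree.tips())
        anchor = min(leaves)
        key = frozenset(leaves - side) if anchor in side else side
        if key in counts:
            node.support = 100.0 * counts[key] / n_ok
    return ref_tree


def set_outgroup(tree: TreeNode, leaf_id: str) -> TreeNode:
    """Rooted *view* of the tree with ``leaf_id`` as outgroup; the
    unrooted topology is unchanged (a copy is rooted for display)."""
    t = tree.copy()
    try:
        leaf = t.find(leaf_id)
    except Exception:
        raise PhyloError(f"unknown leaf {leaf_id!r}") from None
    if not leaf.is_tip():
        raise PhyloError(f"{leaf_id!r} is not a leaf")
    try:
        return t.root_at(leaf, above=True)
    except TypeError:  # pragma: no cover - older skbio without `above`
        return t.root_at(leaf.parent)


def write_newick(
    tree: TreeNode,
    path=None,
    support_as: str = "label",
    clamp_negative: bool = False,
) -> str:
    """Serialise to Newick; bootstrap supports become internal-node
    labels (default) or bracket comments. Returns the Newick string."""
    t = tree.copy()
    for node in t.non_tips(include_self=False):
        sup = getattr(node, "support", None)
        if sup is not None:
            if support_as == "label":
                # skbio serialises .support into the internal-node label
                node.support = int(round(sup))
                node.name = None
            elif support_as == "comment":
                node.support = None
                node.name = f"[{int(round(sup))}]"
    if clamp_negative:
        for node in t.traverse():
            if node.length is not None and node.length < 0:
                node.length = 0.0
    buf = io.StringIO()
    t.write(buf, format="newick")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_newick(source) -> TreeNode:
    return TreeNode.read(source, format="newick")
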