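"""Unrooted phylogenetic trees over a fixed taxon ordering.

Trees are stored as adjacency maps on integer node ids: leaves are
``0..n_taxa-1`` (positions in ``taxa``), internal nodes are larger ids.
Topology identity is judged by the set of nontrivial unrooted splits
(bipartitions), each encoded as an integer bitmask over taxon positions,
canonically oriented to the side *not* containing taxon 0.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

__all__ = ["PhyloTree", "strict_consensus", "tree_from_splits", "parse_newick"]


def _canon(mask: int, full: int) -> int:
    """Canonical orientation of a bipartition: the side without taxon 0."""
    return (mask ^ full) if (mask & 1) else mask


@dataclass
class PhyloTree:
    """Unrooted tree; internal nodes have degree >= 3 (no degree-2 nodes)."""

    taxa: tuple
    adj: dict  # node id -> set of neighbour ids
    root_taxon: str | None = None  # optional display root

    def __post_init__(self) -> None:
        # invariant (maintained by all public constructors, not re-checked
        # here so search code can pass through intermediate states): internal
        # nodes have degree >= 3
        self.taxa = tuple(self.taxa)

    # -- construction ------------------------------------------------------
    @classmethod
    def star(cls, taxa) -> "PhyloTree":
        taxa = tuple(taxa)
        n = len(taxa)
        hub = n
        adj = {hub: set(range(n))}
        for i in range(n):
            adj[i] = {hub}
        return cls(taxa=taxa, adj=adj)

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            taxa=self.taxa,
            adj={u: set(v) for u, v in self.adj.items()},
            root_taxon=self.root_taxon,
        )

    # -- basic queries -----------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def is_binary(self) -> bool:
        return all(
            len(nbrs) == 3 for node, nbrs in self.adj.items() if node >= self.n_taxa
        )

    def edges(self):
        seen = set()
        for u, nbrs in self.adj.items():
            for v in nbrs:
                if (v, u) not in seen:
                    seen.add((u, v))
                    yield (u, v)

    def postorder(self, root: int):
        """(node, parent) pairs, children before parents, root last."""
        out, stack = [], [(root, None)]
        while stack:
            node, parent = stack.pop()
            out.append((node, parent))
            for nbr in self.adj[node]:
                if nbr != parent:
                    stack.append((nbr, node))
        return out[::-1]

    def splits(self) -> frozenset:
        """Nontrivial unrooted splits as canonical bitmasks."""
        n = self.n_taxa
        full = (1 << n) - 1
        below = {}
        order = self.postorder(root=0)
        result = set()
        for node, parent in order:
            if node < n:
                below[node] = 1 << node
            else:
                mask = 0
                for nbr in self.adj[node]:
                    if nbr != parent:
                        mask |= below[nbr]
                below[node] = mask
            if parent is not None:
                m = below[node]
                k = bin(m).count("1")
                if 2 <= k <= n - 2:
                    result.add(_canon(m, full))
        return frozenset(result)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return self.taxa == other.taxa and self.splits() == other.splits()

    def __hash__(self) -> int:
        return hash((self.taxa, self.splits()))

    # -- newick ------------------------------------------------------------
    def to_newick(self, support: dict | None = None, root_taxon: str | None = None) -> str:
        """Newick string, rooted for display on ``root_taxon`` (a leaf).

        ``support`` maps canonical split masks -> percentage; rendered as
        integer internal-node labels.
        """
        n = self.n_taxa
        full = (1 << n) - 1
        root_taxon = root_taxon or self.root_taxon or self.taxa[0]
        root = self.taxa.index(root_taxon)
        masks = {}

        def mask_of(node, parent):
            if node < n:
                return 1 << node
            return masks[(node, parent)]

        # precompute subtree masks
        for node, parent in self.postorder(root):
            if node >= n:
                m = 0
                for nbr in self.adj[node]:
                    if nbr != parent:
                        m |= mask_of(nbr, node)
                masks[(node, parent)] = m

        buf = io.StringIO()

        def write(node, parent):
            if node < n:
                buf.write(self.taxa[node])
                return
            buf.write("(")
            children = [nbr for nbr in self.adj[node] if nbr != parent]
            for i, ch in enumerate(children):
                if i:
                    buf.write(",")
                write(ch, node)
            buf.write(")")
            if support is not None:
                m = _canon(masks[(node, parent)], full)
                if m in support:
                    buf.write(str(int(round(support[m]))))

        hub = next(iter(self.adj[root]))
        buf.write("(")
        buf.write(self.taxa[root])
        for nbr in self.adj[hub]:
            if nbr != root:
                buf.write(",")
                write(nbr, hub)
        buf.write(");")
        return buf.getvalue()


def parse_newick(text: str, taxa=None) -> PhyloTree:
    """Parse a newick string into a :class:`PhyloTree` (labels ignored)."""
    import dendropy

    dtree = dendropy.Tree.get(data=text, schema="newick")
    labels = sorted(l.taxon.label.replace(" ", "_") for l in dtree.leaf_node_iter())
    taxa = tuple(taxa) if taxa is not None else tuple(labels)
    index = {t: i for i, t in enumerate(taxa)}
    adj: dict = {}
    next_id = len(taxa)
    node_ids = {}

    def get_id(node):
        nonlocal next_id
        if node in node_ids:
            return node_ids[node]
        if node.is_leaf():
            nid = index[node.taxon.label.replace(" ", "_")]
        else:
            nid = next_id
            next_id += 1
        node_ids[node] = nid
        adj.setdefault(nid, set())
        return nid

    for edge in dtree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        u, v = get_id(edge.tail_node), get_id(edge.head_node)
        adj[u].add(v)
        adj[v].add(u)
    # suppress degree-2 nodes (dendropy rootings)
    for node in [k for k, v in adj.items() if k >= len(taxa) and len(v) == 2]:
        a, b = adj.pop(node)
        adj[a].discard(node)
        adj[b].discard(node)
        adj[a].add(b)
        adj[b].add(a)
    return PhyloTree(taxa=taxa, adj=adj)


def tree_from_splits(taxa, splits) -> PhyloTree:
    """Build the (possibly multifurcating) tree displaying a compatible split set."""
    taxa = tuple(taxa)
    n = len(taxa)
    full = (1 << n) - 1
    tree = PhyloTree.star(taxa)
    next_id = n + 1
    # insert larger groups first so nesting resolves
    for raw in sorted(splits, key=lambda m: -bin(m).count("1")):
        mask = _canon(raw, full)
        group = [i for i in range(n) if mask >> i & 1]
        # find the node all group leaves currently hang from
        # (walk up from one leaf; with sorted insertion the group's members
        # are all children-subtrees of a single node)
        hub = next(iter(tree.adj[group[0]]))
        members = []
        for nbr in list(tree.adj[hub]):
            sub = _subtree_leafset(tree, nbr, hub)
            if sub & mask and not (sub & ~mask & full):
                members.append(nbr)
        covered = 0
        for nbr in members:
            covered |= _subtree_leafset(tree, nbr, hub)
        if covered != mask or len(members) < 2 or len(members) == len(tree.adj[hub]):
            continue  # incompatible or trivial; skip silently
        new = next_id
        next_id += 1
        tree.adj[new] = set(members) | {hub}
        for nbr in members:
            tree.adj[hub].discard(nbr)
            tree.adj[nbr].discard(hub)
            tree.adj[nbr].add(new)
        tree.adj[hub].add(new)
    return tree


def _subtree_leafset(tree: PhyloTree, node: int, parent: int) -> int:
    mask = 0
    stack = [(node, parent)]
    while stack:
        u, p = stack.pop()
        if u < tree.n_taxa:
            mask |= 1 << u
        for nbr in tree.adj[u]:
            if nbr != p:
                stack.append((nbr, u))
    return mask


def strict_consensus(trees) -> PhyloTree:
    """Tree displaying exactly the splits common to every input tree."""
    trees = list(trees)
    if not trees:
        raise ValueError("need at least one tree")
    taxa = trees[0].taxa
    for t in trees[1:]:
        if t.taxa != taxa:
            raise ValueError("trees have mismatched leaf sets")
    common = trees[0].splits()
    for t in trees[1:]:
        common &= t.splits()
    out = tree_from_splits(taxa, common)
    out.root_taxon = trees[0].root_taxon
    return out
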