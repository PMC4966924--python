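"""Phylogenetic trees with deterministic node numbering.

Trees are stored as a simple parent/child node structure. A tree is
*rooted* when its base node has exactly two children and *unrooted* when
the base is a trifurcation (the usual representation of an unrooted
binary tree). Node identifiers follow the CODEML-style convention: the
``n`` leaves are numbered 1..n in input order and internal nodes are
numbered n+1..2n-1 in post-order, so users of classic reconstruction
pipelines will recognize labels such as "Node7".

Newick parsing is delegated to dendropy; serialization is done here so
that the dialect (branch supports as internal-node labels, no NHX) is
exact and round-trips preserve node numbering.
"""

from __future__ import annotations

import itertools
from typing import Callable, Iterator, Sequence

import dendropy

DEFAULT_BRANCH_LENGTH = 0.1


class NewickError(ValueError):
    """Raised for malformed Newick input."""


class TreeError(ValueError):
    """Raised for structurally invalid tree operations."""


class TreeNode:
    """A node in a :class:`PhyloTree`."""

    __slots__ = ("name", "length", "support", "children", "parent", "node_id",
                 "length_defaulted")

    def __init__(self, name: str | None = None, length: float | None = None):
        self.name = name
        self.length = length  # length of the edge to the parent; None at base
        self.support = None  # branch support of the edge to the parent
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.node_id: int | None = None
        self.length_defaulted = False

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def postorder(self) -> Iterator["TreeNode"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self) -> Iterator["TreeNode"]:
        yield self
        for c in self.children:
            yield from c.preorder()

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def copy(self) -> "TreeNode":
        dup = TreeNode(self.name, self.length)
        dup.support = self.support
        dup.node_id = self.node_id
        dup.length_defaulted = self.length_defaulted
        for c in self.children:
            dup.add_child(c.copy())
        return dup


class PhyloTree:
    """A rooted or unrooted binary phylogeny with branch lengths."""

    def __init__(self, base: TreeNode):
        self.base = base
        self.assign_node_ids()
        self._validate()

    # -- construction / bookkeeping ------------------------------------

    def _validate(self) -> None:
        names = [n.name for n in self.base.leaves()]
        if any(not n for n in names):
            raise TreeError("all leaves must be named")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise TreeError(f"duplicate leaf names: {', '.join(dupes)}")

    def assign_node_ids(self) -> None:
        """Number leaves 1..n in input order, internal nodes post-order."""
        leaves = self.base.leaves()
        for i, leaf in enumerate(leaves, start=1):
            leaf.node_id = i
        next_id = len(leaves) + 1
        for node in self.base.postorder():
            if not node.is_leaf:
                node.node_id = next_id
                next_id += 1

    @property
    def rooted(self) -> bool:
        return len(self.base.children) == 2

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.base.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.base.leaves())

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.base.copy())

    def __repr__(self) -> str:
        kind = "rooted" if self.rooted else "unrooted"
        return f"PhyloTree({kind}, n_leaves={self.n_leaves})"

    # -- queries -------------------------------------------------------

    def postorder(self) -> Iterator[TreeNode]:
        return self.base.postorder()

    def node_by_id(self, node_id: int) -> TreeNode:
        for n in self.base.postorder():
            if n.node_id == node_id:
                return n
        raise KeyError(f"no node with id {node_id}")

    def node_by_name(self, name: str) -> TreeNode:
        for n in self.base.postorder():
            if n.name == name:
                return n
        raise KeyError(f"no leaf named {name!r}")

    def edges(self) -> list[TreeNode]:
        """Every edge, identified by its child node (base excluded)."""
        return [n for n in self.base.postorder() if n.parent is not None]

    def internal_edges(self) -> list[TreeNode]:
        """Internal edges: both endpoints are internal nodes."""
        return [n for n in self.edges() if not n.is_leaf and n.parent is not None]

    def total_branch_length(self) -> float:
        return sum(n.length or 0.0 for n in self.edges())

    def clades(self) -> dict[int, frozenset]:
        """Descendant leaf-name set of every internal node (rooted trees)."""
        out: dict[int, frozenset] = {}
        below: dict[int, set] = {}
        for n in self.base.postorder():
            if n.is_leaf:
                below[id(n)] = {n.name}
            else:
                s: set = set()
                for c in n.children:
                    s |= below[id(c)]
                below[id(n)] = s
                out[n.node_id] = frozenset(s)
        return out

    def mrca(self, names: Sequence[str]) -> TreeNode:
        """Most recent common ancestor of the named leaves (rooted trees)."""
        if not self.rooted:
            raise TreeError("MRCA requires a rooted tree")
        target = set(names)
        missing = target - set(self.leaf_names)
        if missing:
            raise TreeError(f"taxa not in tree: {sorted(missing)}")
        for n in self.base.postorder():
            leafset = {x.name for x in n.leaves()} if not n.is_leaf else {n.name}
            if target <= leafset:
                return n
        return self.base

    def bipartitions(self, restrict: set | None = None) -> set:
        """Nontrivial bipartitions as canonical frozensets of leaf names.

        Each internal edge splits the leaves in two; the side not
        containing the alphabetically first (restricted) leaf is the
        canonical representative. ``restrict`` intersects every split
        with a taxon subset first (used for constraint checking).
        """
        all_names = set(self.leaf_names)
        if restrict is not None:
            all_names = all_names & set(restrict)
        if len(all_names) < 4:
            return set()
        anchor = min(all_names)
        splits = set()
        for n in self.base.postorder():
            if n.is_leaf or n.parent is None:
                continue
            side = {x.name for x in n.leaves()} & all_names
            if anchor in side:
                side = all_names - side
            if 1 < len(side) < len(all_names) - 1:
                splits.add(frozenset(side))
        # a rooted base contributes no extra split beyond its children's
        return splits

    # -- topology surgery ----------------------------------------------

    def unrooted(self) -> "PhyloTree":
        """Collapse a degree-2 base into a trifurcation (new tree)."""
        if not self.rooted:
            return self.copy()
        if self.n_leaves < 3:
            raise TreeError("cannot unroot a tree with fewer than 3 leaves")
        base = self.base.copy()
        left, right = base.children
        internal = left if not left.is_leaf else right
        other = right if internal is left else left
        if internal.is_leaf:
            raise TreeError("cannot unroot: base joins two leaves")
        # merge the two base edges into one
        other.length = (other.length or 0.0) + (internal.length or 0.0)
        new_base = TreeNode()
        for c in internal.children:
            new_base.add_child(c)
        new_base.add_child(other)
        return PhyloTree(new_base)

    def rebased_at(self, node_id: int) -> "PhyloTree":
        """Re-base an unrooted tree at an internal node (same topology)."""
        if self.rooted:
            raise TreeError("rebase applies to unrooted trees")
        tree = self.copy()
        node = tree.node_by_id(node_id)
        if node.is_leaf:
            raise TreeError("cannot base an unrooted tree at a leaf")
        _reorient(node)
        return PhyloTree(node)

    def rooted_on_edge(self, child_id: int, fraction: float = 0.5) -> "PhyloTree":
        """Root by inserting a degree-2 node on the edge above ``child_id``.

        ``fraction`` of the edge length goes to the child side.
        """
        tree = self.copy()
        child = tree.node_by_id(child_id)
        if child.parent is None:
            raise TreeError("cannot root on the base node")
        parent = child.parent
        parent.children.remove(child)
        child.parent = None
        _reorient(parent)  # parent becomes temporary base of the other side
        t = child.length if child.length is not None else 0.0
        root = TreeNode()
        child.length = t * fraction
        parent.length = t * (1.0 - fraction)
        parent.support = child.support
        root.add_child(child)
        root.add_child(parent)
        return PhyloTree(root)


def _reorient(node: TreeNode) -> None:
    """Make ``node`` the base by flipping parent links along its path up."""
    path = []
    cur = node
    while cur.parent is not None:
        path.append(cur)
        cur = cur.parent
    for child in reversed(path):
        parent = child.parent
        parent.children.remove(child)
        # parent becomes a child of child, inheriting the edge
        parent.length = child.length
        parent.support = child.support
        child.length = None
        child.support = None
        parent.parent = None
        child.parent = None
        child.add_child(parent)
    node.parent = None
    node.length = None
    node.support = None


# ----------------------------------------------------------------------
# Newick I/O


def read_newick(source: str, rooted: bool | None = None) -> PhyloTree:
    """Parse a Newick string or file path into a :class:`PhyloTree`.

    Missing branch lengths default to 0.1 and are flagged as defaulted.
    Internal-node labels are read as branch supports when numeric. A
    degree-2 base is collapsed to a trifurcation (the tree is treated as
    unrooted) unless ``rooted=True`` or the tree has only two leaves;
    ``rooted=False`` forces collapsing, ``None`` applies the default.
    """
    text = source
    if "(" not in source:
        with open(source) as fh:
            text = fh.read()
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"could not parse Newick: {exc}") from exc

    def convert(dnode) -> TreeNode:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = TreeNode(name=label)
        else:
            node = TreeNode()
            if dnode.label not in (None, ""):
                try:
                    node.support = float(dnode.label)
                except ValueError:
                    node.name = dnode.label
        if dnode.edge.length is None:
            node.length = DEFAULT_BRANCH_LENGTH
            node.length_defaulted = True
        else:
            node.length = float(dnode.edge.length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    base = convert(dtree.seed_node)
    base.length = None
    base.length_defaulted = False
    tree = PhyloTree(base)
    if rooted is not True and tree.rooted and tree.n_leaves >= 3:
        tree = tree.unrooted()
    return tree


def write_newick(tree: PhyloTree, with_support: bool = False,
                 precision: int = 10) -> str:
    """Serialize to Newick. Branch supports become internal-node labels."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            s = node.name
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if with_support and node.support is not None:
                s += f"{node.support:.{6}g}"
        if node.parent is not None and node.length is not None:
            s += f":{node.length:.{precision}g}"
        return s

    return fmt(tree.base) + ";"


# ----------------------------------------------------------------------
# Topology generation


def enumerate_topologies(taxa: Sequence[str],
                         branch_length: float = DEFAULT_BRANCH_LENGTH
                         ) -> Iterator[PhyloTree]:
    """All unrooted binary topologies on the taxa, by stepwise addition.

    Yields (2n-5)!! trees in a deterministic order; every branch length
    is initialized to ``branch_length``.
    """
    taxa = list(taxa)
    if len(taxa) < 3:
        raise TreeError("need at least 3 taxa to enumerate unrooted trees")

    def build(shape) -> TreeNode:
        if isinstance(shape, str):
            return TreeNode(shape, branch_length)
        node = TreeNode(None, branch_length)
        for sub in shape:
            node.add_child(build(sub))
        return node

    def grow(shape, taxon):
        """Yield shapes with ``taxon`` attached to each edge of ``shape``."""
        # shape is a tuple of 3 subtrees (unrooted base); edges live inside
        def attach(sub, taxon):
            # yield all versions of sub with taxon inserted on an edge in sub
            yield (sub, taxon)  # attach on the edge above sub
            if not isinstance(sub, str):
                for i, branch in enumerate(sub):
                    for new_branch in attach(branch, taxon):
                        yield tuple(new_branch if j == i else b
                                    for j, b in enumerate(sub))

        for i, branch in enumerate(shape):
            for new_branch in attach(branch, taxon):
                yield tuple(new_branch if j == i else b
                            for j, b in enumerate(shape))

    shapes = [(taxa[0], taxa[1], taxa[2])]
    for taxon in taxa[3:]:
        shapes = [s for old in shapes for s in grow(old, taxon)]
    for shape in shapes:
        base = TreeNode()
        for sub in shape:
            base.add_child(build(sub))
        base.length = None
        yield PhyloTree(base)


def canonical_topology(tree: PhyloTree) -> str:
    """Topology-only canonical string (sorted children, no lengths)."""

    def key(node: TreeNode) -> str:
        if node.is_leaf:
            return node.name
        return "(" + ",".join(sorted(key(c) for c in node.children)) + ")"

    if tree.rooted:
        return key(tree.base) + ";"
    # canonical base for unrooted trees: rebase at the internal node
    # adjacent to the alphabetically first leaf
    first = min(tree.leaf_names)
    t = tree.copy()
    leaf = t.node_by_name(first)
    if leaf.parent is not t.base:
        t = t.rebased_at(leaf.parent.node_id)
    return key(t.base) + ";"


def same_topology(a: PhyloTree, b: PhyloTree) -> bool:
    if set(a.leaf_names) != set(b.leaf_names):
        return False
    if a.rooted != b.rooted:
        return False
    if a.rooted:
        return canonical_topology(a) == canonical_topology(b)
    return a.bipartitions() == b.bipartitions() and set(a.leaf_names) == set(b.leaf_names)


def nni_neighbors(tree: PhyloTree, edge_child_id: int) -> list[PhyloTree]:
    """The two nearest-neighbor-interchange rearrangements of an edge.

    The edge is identified by its child node id and must be internal.
    Branch lengths are carried over unchanged; the two alternatives swap
    one subtree on the child side with one on the parent side.
    """
    work = tree.copy()
    child = work.node_by_id(edge_child_id)
    if child.is_leaf or child.parent is None:
        raise TreeError("NNI requires an internal edge")
    parent = child.parent
    if not work.rooted and parent.parent is not None:
        # re-base so the parent side's subtrees are plain children
        work = work.rebased_at(parent.node_id)
        # re-locate the focal child: same descendant leaf set
        target = {l.name for l in child.leaves()}
        child = next(n for n in work.base.children
                     if {l.name for l in n.leaves()} == target)
        parent = work.base
    out = []
    siblings = [c for c in parent.children if c is not child]
    sib = siblings[0]
    for grand in list(child.children):
        variant = work.copy()
        v_child = variant.node_by_id(child.node_id)
        v_parent = v_child.parent
        v_sib = next(c for c in v_parent.children
                     if {l.name for l in c.leaves()} == {l.name for l in sib.leaves()})
        v_grand = next(c for c in v_child.children
                       if {l.name for l in c.leaves()} == {l.name for l in grand.leaves()})
        # swap v_sib and v_grand
        v_parent.children[v_parent.children.index(v_sib)] = v_grand
        v_child.children[v_child.children.index(v_grand)] = v_sib
        v_sib.parent, v_grand.parent = v_child, v_parent
        out.append(PhyloTree(variant.base))
    return out


def random_topology(taxa: Sequence[str], rng) -> PhyloTree:
    """A uniform random unrooted binary topology (stepwise addition)."""
    taxa = list(taxa)
    if len(taxa) < 3:
        raise TreeError("need at least 3 taxa")
    base = TreeNode()
    for t in taxa[:3]:
        base.add_child(TreeNode(t, DEFAULT_BRANCH_LENGTH))
    tree = PhyloTree(base)
    for taxon in taxa[3:]:
        edges = tree.edges()
        target = edges[rng.integers(len(edges))]
        parent = target.parent
        new_internal = TreeNode(None, DEFAULT_BRANCH_LENGTH)
        parent.children[parent.children.index(target)] = new_internal
        new_internal.parent = parent
        new_internal.add_child(target)
        new_internal.add_child(TreeNode(taxon, DEFAULT_BRANCH_LENGTH))
        tree = PhyloTree(tree.base)
    return tree
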