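"""Unrooted leaf-labelled phylogenetic trees: Newick I/O, bipartitions, restriction, RF.

This module is the substrate for everything else in the package.  A tree is
stored as a plain undirected graph (adjacency sets over opaque integer node
ids) with a bijection between leaf nodes and taxon-name strings.  Branch
lengths are carried as metadata only; no algorithm in the package uses them.

All serialization is canonical and deterministic: a tree is written as a
trifurcation at the internal node adjacent to the lexicographically smallest
leaf, with children ordered by their smallest descendant label, so two trees
with equal topology produce byte-identical Newick strings.
"""

from __future__ import annotations

import io
import itertools
from typing import Dict, FrozenSet, Iterator, List, Optional, Set, Tuple

import dendropy

from .errors import LeafSetError, NewickParseError, NotBinaryError, TreeValidationError

__all__ = [
    "UnrootedTree",
    "Bipartition",
    "RootedView",
    "parse_newick",
    "parse_newick_file",
    "write_newick",
    "bipartitions",
    "restrict",
    "rf_distance",
    "normalized_rf",
    "root_at_leaf_and_prune",
]

Edge = FrozenSet[int]


class Bipartition:
    """A split A|B of a leaf set, the unit of all RF machinery.

    Canonical form: ``side_a`` is the side containing the lexicographically
    smallest taxon.  Equality and hashing depend only on the unordered pair
    of sides, which the canonical form makes directly comparable.
    """

    __slots__ = ("side_a", "side_b", "_hash")

    def __init__(self, side_a, side_b):
        a = frozenset(side_a)
        b = frozenset(side_b)
        if not a or not b:
            raise TreeValidationError("bipartition sides must be non-empty")
        if a & b:
            raise TreeValidationError("bipartition sides must be disjoint")
        if min(a) > min(b):
            a, b = b, a
        self.side_a = a
        self.side_b = b
        self._hash = hash((self.side_a, self.side_b))

    @property
    def leaf_set(self) -> FrozenSet[str]:
        return self.side_a | self.side_b

    @property
    def is_trivial(self) -> bool:
        return min(len(self.side_a), len(self.side_b)) == 1

    def restrict(self, subset) -> Optional["Bipartition"]:
        """Induced split on ``subset``, or None when one side empties out."""
        subset = frozenset(subset)
        a = self.side_a & subset
        b = self.side_b & subset
        if not a or not b:
            return None
        return Bipartition(a, b)

    def sort_key(self) -> tuple:
        """Deterministic total order over bipartitions of one leaf set."""
        return (tuple(sorted(self.side_a)), tuple(sorted(self.side_b)))

    def __eq__(self, other):
        if not isinstance(other, Bipartition):
            return NotImplemented
        return self.side_a == other.side_a and self.side_b == other.side_b

    def __hash__(self):
        return self._hash

    def __repr__(self):
        fmt = lambda s: ",".join(sorted(s))
        return f"Bipartition({fmt(self.side_a)} | {fmt(self.side_b)})"


class UnrootedTree:
    """Unrooted leaf-labelled phylogenetic tree over an undirected graph.

    Invariants: connected, acyclic; leaves (degree-1 nodes) carry unique
    non-empty labels; internal nodes are unlabelled.  Binary means every
    internal node has degree exactly 3.
    """

    def __init__(self):
        self._adj: Dict[int, Set[int]] = {}
        self._label: Dict[int, str] = {}
        self._node_of: Dict[str, int] = {}
        self._length: Dict[Edge, float] = {}
        self._next_id = 0

    # -- construction ------------------------------------------------------

    def _new_node(self, label: Optional[str] = None) -> int:
        nid = self._next_id
        self._next_id += 1
        self._adj[nid] = set()
        if label is not None:
            if not label:
                raise TreeValidationError("leaf labels must be non-empty")
            if label in self._node_of:
                raise TreeValidationError(f"duplicate leaf label {label!r}")
            self._label[nid] = label
            self._node_of[label] = nid
        return nid

    def _add_edge(self, u: int, v: int, length: Optional[float] = None) -> None:
        self._adj[u].add(v)
        self._adj[v].add(u)
        if length is not None:
            self._length[frozenset((u, v))] = length

    def _remove_edge(self, u: int, v: int) -> None:
        self._adj[u].discard(v)
        self._adj[v].discard(u)
        self._length.pop(frozenset((u, v)), None)

    def _remove_node(self, u: int) -> None:
        for v in list(self._adj[u]):
            self._remove_edge(u, v)
        del self._adj[u]
        lab = self._label.pop(u, None)
        if lab is not None:
            del self._node_of[lab]

    # -- basic queries -----------------------------------------------------

    @property
    def leaf_labels(self) -> FrozenSet[str]:
        return frozenset(self._node_of)

    @property
    def n_leaves(self) -> int:
        return len(self._node_of)

    def nodes(self) -> Iterator[int]:
        return iter(self._adj)

    def edges(self) -> List[Tuple[int, int]]:
        out = []
        for u, nbrs in self._adj.items():
            for v in nbrs:
                if u < v:
                    out.append((u, v))
        return out

    def degree(self, u: int) -> int:
        return len(self._adj[u])

    def neighbors(self, u: int) -> Set[int]:
        return set(self._adj[u])

    def is_leaf(self, u: int) -> bool:
        return u in self._label

    def label_of(self, u: int) -> Optional[str]:
        return self._label.get(u)

    def node_of(self, label: str) -> int:
        try:
            return self._node_of[label]
        except KeyError:
            raise LeafSetError(
                f"taxon {label!r} not in tree", only_in_b=[label]
            ) from None

    def branch_length(self, u: int, v: int) -> Optional[float]:
        return self._length.get(frozenset((u, v)))

    def is_binary(self) -> bool:
        if self.n_leaves < 3:
            return len(self._adj) == self.n_leaves  # a single edge or node
        return all(
            len(nbrs) == (1 if u in self._label else 3)
            for u, nbrs in self._adj.items()
        )

    def copy(self) -> "UnrootedTree":
        t = UnrootedTree()
        t._adj = {u: set(nbrs) for u, nbrs in self._adj.items()}
        t._label = dict(self._label)
        t._node_of = dict(self._node_of)
        t._length = dict(self._length)
        t._next_id = self._next_id
        return t

    # -- structural edits used by completion / simulation ------------------

    def subdivide_edge(self, u: int, v: int) -> int:
        """Insert a new degree-2 node in the middle of edge (u, v)."""
        if v not in self._adj[u]:
            raise TreeValidationError(f"no edge between nodes {u} and {v}")
        self._remove_edge(u, v)
        w = self._new_node()
        self._add_edge(u, w)
        self._add_edge(w, v)
        return w

    def attach_leaf(self, at: int, label: str) -> int:
        """Attach a new labelled leaf to an existing node."""
        leaf = self._new_node(label)
        self._add_edge(at, leaf)
        return leaf

    def add_leaf_on_edge(self, u: int, v: int, label: str) -> int:
        """Subdivide edge (u, v) and hang a new leaf off the midpoint."""
        w = self.subdivide_edge(u, v)
        return self.attach_leaf(w, label)

    def suppress_degree_two(self) -> None:
        """Splice out every unlabelled degree-2 node, summing branch lengths."""
        for u in [n for n in self._adj if len(self._adj[n]) == 2 and n not in self._label]:
            a, b = self._adj[u]
            la = self._length.get(frozenset((a, u)))
            lb = self._length.get(frozenset((u, b)))
            self._remove_node(u)
            length = la + lb if (la is not None and lb is not None) else None
            self._add_edge(a, b, length)

    # -- traversal ---------------------------------------------------------

    def side_leaves(self, u: int, v: int) -> FrozenSet[str]:
        """Taxa on the v-side of edge (u, v)."""
        seen = {u, v}
        stack = [v]
        out = []
        while stack:
            w = stack.pop()
            lab = self._label.get(w)
            if lab is not None:
                out.append(lab)
            for x in self._adj[w]:
                if x not in seen:
                    seen.add(x)
                    stack.append(x)
        return frozenset(out)

    # -- equality / display --------------------------------------------------

    def topology_key(self) -> FrozenSet:
        """Hashable identity: leaf set plus the full bipartition set."""
        return frozenset((self.leaf_labels, frozenset(bipartitions(self, include_trivial=True))))

    def __eq__(self, other):
        if not isinstance(other, UnrootedTree):
            return NotImplemented
        if self.leaf_labels != other.leaf_labels:
            return False
        return bipartitions(self, include_trivial=True) == bipartitions(
            other, include_trivial=True
        )

    def __hash__(self):
        return hash(self.topology_key())

    def __repr__(self):
        return f"UnrootedTree(n_leaves={self.n_leaves})"

    def __str__(self):
        return write_newick(self)


class RootedView:
    """Rooted perspective on an unrooted tree, as produced by rooting at a
    leaf x and deleting x together with its incident edge.

    The root has exactly two children; child order is deterministic (by
    smallest descendant leaf label) so depth-first traversals are
    reproducible.  ``clade(v)`` is the set of taxa below node v.
    """

    def __init__(self, root: int, children: Dict[int, List[int]],
                 clades: Dict[int, FrozenSet[str]], pruned_leaf: str):
        self.root = root
        self._children = children
        self._clades = clades
        self.pruned_leaf = pruned_leaf

    def children(self, u: int) -> List[int]:
        return self._children.get(u, [])

    def clade(self, u: int) -> FrozenSet[str]:
        return self._clades[u]

    @property
    def leaf_labels(self) -> FrozenSet[str]:
        return self._clades[self.root]

    def edges_preorder(self) -> Iterator[Tuple[int, int]]:
        """(parent, child) edges in depth-first preorder from the root."""
        stack = list(reversed(self._children[self.root]))
        parents = {c: self.root for c in self._children[self.root]}
        while stack:
            v = stack.pop()
            yield parents[v], v
            kids = self._children.get(v, [])
            for c in reversed(kids):
                parents[c] = v
                stack.append(c)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def _from_dendropy(dtree: "dendropy.Tree") -> UnrootedTree:
    tree = UnrootedTree()
    node_map: Dict[object, int] = {}
    for nd in dtree.preorder_node_iter():
        label = None
        if nd.is_leaf():
            if nd.taxon is None or nd.taxon.label is None:
                raise NewickParseError("leaf without a label")
            label = str(nd.taxon.label)
        node_map[nd] = tree._new_node(label)
    for nd in dtree.preorder_node_iter():
        if nd.parent_node is not None:
            tree._add_edge(node_map[nd.parent_node], node_map[nd],
                           nd.edge.length)
    tree.suppress_degree_two()
    if len(tree._adj) > 1 and any(len(n) == 0 for n in tree._adj.values()):
        raise TreeValidationError("tree graph is disconnected")
    return tree


def parse_newick(text: str) -> UnrootedTree:
    """Parse a single Newick statement into an :class:`UnrootedTree`.

    A bifurcating Newick root is suppressed, so rooted and unrooted
    serializations of the same topology compare equal.  Quoted labels and
    branch lengths are preserved; internal node labels are ignored.
    """
    if not text.strip():
        raise NewickParseError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        if "Duplicate taxon labels" in str(exc):
            raise TreeValidationError(f"duplicate leaf labels: {exc}") from exc
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(dtree)


def parse_newick_file(path) -> List[UnrootedTree]:
    """Read a file with one Newick tree per line (blank lines skipped)."""
    trees = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                trees.append(parse_newick(line))
            except NewickParseError as exc:
                raise NewickParseError(f"{path}:{i}: {exc}") from exc
    return trees


def _min_descendant(tree: UnrootedTree, u: int, parent: int,
                    cache: Dict[Tuple[int, int], str]) -> str:
    key = (parent, u)
    if key in cache:
        return cache[key]
    lab = tree.label_of(u)
    if lab is None:
        lab = min(
            _min_descendant(tree, v, u, cache)
            for v in tree.neighbors(u)
            if v != parent
        )
    cache[key] = lab
    return lab


def _write_subtree(tree: UnrootedTree, u: int, parent: int,
                   cache, include_lengths: bool) -> str:
    lab = tree.label_of(u)
    if lab is None:
        kids = sorted(
            (v for v in tree.neighbors(u) if v != parent),
            key=lambda v: _min_descendant(tree, v, u, cache),
        )
        body = "(" + ",".join(
            _write_subtree(tree, v, u, cache, include_lengths) for v in kids
        ) + ")"
    else:
        body = _quote_label(lab)
    if include_lengths and parent is not None:
        length = tree.branch_length(parent, u)
        if length is not None:
            body += f":{length:g}"
    return body


def _quote_label(label: str) -> str:
    if any(c in label for c in "()[]{}:;,'\" \t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: UnrootedTree, include_lengths: bool = False) -> str:
    """Canonical Newick string; serialized as a trifurcation at the internal
    node adjacent to the lexicographically smallest leaf."""
    if tree.n_leaves == 0:
        raise TreeValidationError("cannot serialize an empty tree")
    if tree.n_leaves == 1:
        (label,) = tree.leaf_labels
        return _quote_label(label) + ";"
    smallest = min(tree.leaf_labels)
    leaf = tree.node_of(smallest)
    (anchor,) = tree.neighbors(leaf)
    cache: Dict[Tuple[int, int], str] = {}
    if tree.is_leaf(anchor):  # two-leaf tree
        a, b = sorted(tree.leaf_labels)
        s = f"({_quote_label(a)},{_quote_label(b)}"
        if include_lengths:
            length = tree.branch_length(leaf, anchor)
            if length is not None:
                s += f":{length:g}"
        return s + ");"
    kids = sorted(
        tree.neighbors(anchor),
        key=lambda v: _min_descendant(tree, v, anchor, cache),
    )
    return (
        "("
        + ",".join(_write_subtree(tree, v, anchor, cache, include_lengths) for v in kids)
        + ");"
    )


# ---------------------------------------------------------------------------
# Bipartitions, restriction, RF
# ---------------------------------------------------------------------------

def bipartitions(tree: UnrootedTree, include_trivial: bool = False) -> FrozenSet[Bipartition]:
    """The set C(T): one split per edge (internal edges only by default).

    For an n-leaf binary tree there are n - 3 nontrivial bipartitions.
    """
    if tree.n_leaves < 2:
        raise TreeValidationError("bipartitions need at least 2 leaves")
    all_leaves = tree.leaf_labels
    out = set()
    for u, v in tree.edges():
        side = tree.side_leaves(u, v)
        if not side or side == all_leaves:
            continue
        bip = Bipartition(side, all_leaves - side)
        if include_trivial or not bip.is_trivial:
            out.add(bip)
    return frozenset(out)


def bipartition_edge_map(tree: UnrootedTree, include_trivial: bool = True
                         ) -> Dict[Bipartition, Tuple[int, int]]:
    """Map each split of the tree to the edge (u, v) that induces it."""
    all_leaves = tree.leaf_labels
    out: Dict[Bipartition, Tuple[int, int]] = {}
    for u, v in tree.edges():
        side = tree.side_leaves(u, v)
        if not side or side == all_leaves:
            continue
        bip = Bipartition(side, all_leaves - side)
        if include_trivial or not bip.is_trivial:
            out[bip] = (u, v)
    return out


def restrict(tree: UnrootedTree, subset) -> UnrootedTree:
    """T restricted to a taxon subset: the minimal connecting subtree with
    degree-2 nodes suppressed."""
    subset = frozenset(subset)
    missing = subset - tree.leaf_labels
    if missing:
        raise LeafSetError(
            f"taxa not in tree: {sorted(missing)}", only_in_b=missing
        )
    if len(subset) < 2:
        raise TreeValidationError("restriction needs at least 2 taxa")
    t = tree.copy()
    # iteratively prune leaves outside the subset
    frontier = [u for u, lab in list(t._label.items()) if lab not in subset]
    while frontier:
        u = frontier.pop()
        (v,) = t._adj[u]
        t._remove_node(u)
        if len(t._adj[v]) == 1 and v not in t._label:
            frontier.append(v)
    t.suppress_degree_two()
    return t


def _require_same_leaves(t1: UnrootedTree, t2: UnrootedTree) -> FrozenSet[str]:
    l1, l2 = t1.leaf_labels, t2.leaf_labels
    if l1 != l2:
        raise LeafSetError(
            f"leaf sets differ: only in first {sorted(l1 - l2)}, "
            f"only in second {sorted(l2 - l1)}",
            only_in_a=l1 - l2,
            only_in_b=l2 - l1,
        )
    return l1


def rf_distance(t1: UnrootedTree, t2: UnrootedTree) -> int:
    """Robinson–Foulds distance: |C(t1) Δ C(t2)| over nontrivial splits."""
    leaves = _require_same_leaves(t1, t2)
    if len(leaves) < 3:
        raise TreeValidationError("RF distance needs at least 3 shared leaves")
    return len(bipartitions(t1) ^ bipartitions(t2))


def normalized_rf(t1: UnrootedTree, t2: UnrootedTree) -> float:
    """RF divided by the total internal-edge count of the two trees.

    Equals RF / (2(n-3)) for two binary n-leaf trees; 0 iff identical
    topology, 1 iff no shared nontrivial split.
    """
    b1, b2 = bipartitions(t1), bipartitions(t2)
    _require_same_leaves(t1, t2)
    denom = len(b1) + len(b2)
    if denom == 0:
        raise TreeValidationError(
            "normalized RF undefined: both trees are stars (no internal edges)"
        )
    return len(b1 ^ b2) / denom


def root_at_leaf_and_prune(tree: UnrootedTree, x: str) -> RootedView:
    """Root the tree at leaf x, then delete x and its incident edge.

    The result is the rooted binary tree the leaf-addition step walks: its
    root (x's former neighbour) has exactly two children, and every node
    carries the set of taxa below it.
    """
    if tree.n_leaves < 3:
        raise TreeValidationError("rooting-and-pruning needs at least 3 leaves")
    leaf = tree.node_of(x)
    (root,) = tree.neighbors(leaf)
    children: Dict[int, List[int]] = {}
    clades: Dict[int, FrozenSet[str]] = {}

    def build(u: int, parent: int) -> FrozenSet[str]:
        lab = tree.label_of(u)
        if lab is not None:
            clades[u] = frozenset((lab,))
            return clades[u]
        kids = [v for v in tree.neighbors(u) if v != parent]
        sub = [(build(v, u), v) for v in kids]
        sub.sort(key=lambda p: min(p[0]))
        children[u] = [v for _, v in sub]
        clades[u] = frozenset().union(*(c for c, _ in sub))
        return clades[u]

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * len(tree._adj) + 100))
    try:
        build(root, leaf)
    finally:
        sys.setrecursionlimit(old)
    return RootedView(root, children, clades, pruned_leaf=x)
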