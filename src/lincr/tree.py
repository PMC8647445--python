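"""Rooted phylogenetic trees: data model, Newick I/O, clusters and triples.

A rooted phylogenetic tree is a rooted tree in which every inner vertex has
at least two children and every leaf carries a unique taxon label.  The
central set-theoretic view of such a tree is its *cluster system*
``H(T) = { L(T(v)) : v in V(T) }``, the family of leaf-label sets of its
subtrees.  ``H(T)`` is a hierarchy (a laminar family containing the full
leaf set and all singletons), and the map ``T -> H(T)`` is a bijection
between rooted phylogenetic trees on a leaf set ``L`` and hierarchies on
``L``: the tree can be recovered as the Hasse diagram of its clusters under
set inclusion.  Everything in this package -- refinement, display, rooted
triples, tree compatibility -- is defined through clusters, and this module
provides those primitives.

Vertices are opaque objects; identity is object identity, never a label.
This matters for the refinement algorithm in :mod:`lincr.merge`, which keeps
cross-tree correspondence tables between vertices of different trees.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import dendropy

__all__ = [
    "Cluster",
    "ClusterSystem",
    "InputError",
    "NewickError",
    "RootedTree",
    "Triple",
    "Vertex",
    "cluster_map",
    "clusters",
    "contract_edge",
    "displays_same_leafset",
    "is_hierarchy",
    "isomorphic",
    "lca",
    "parse_newick",
    "tree_from_hierarchy",
    "triples",
    "write_newick",
]


class InputError(ValueError):
    """An input violates a documented precondition."""


class NewickError(InputError):
    """A Newick string cannot be parsed."""


#: A cluster is represented as a plain frozenset of leaf labels.
Cluster = frozenset


class Vertex:
    """Opaque tree vertex with parent/children links and an optional label.

    Leaves carry their taxon label in :attr:`label`; inner vertices may carry
    an (optional) inner label.  Identity is object identity.
    """

    __slots__ = ("parent", "children", "label")

    def __init__(self, label: str | None = None) -> None:
        self.parent: Vertex | None = None
        self.children: list[Vertex] = []
        self.label = label

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Vertex") -> None:
        child.parent = self
        self.children.append(child)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.label is not None:
            return f"<Vertex {self.label!r}>"
        return f"<Vertex at {id(self):#x}>"


class RootedTree:
    """A rooted tree over :class:`Vertex` objects.

    Child order is preserved from construction but carries no semantics: all
    equality predicates in this package are cluster-based and therefore
    order-insensitive.
    """

    def __init__(self, root: Vertex) -> None:
        self.root = root

    # -- traversals (iterative: trees may be deep) --------------------------

    def preorder(self) -> Iterator[Vertex]:
        stack = [self.root]
        while stack:
            v = stack.pop()
            yield v
            stack.extend(reversed(v.children))

    def postorder(self) -> Iterator[Vertex]:
        # In a preorder sequence every parent precedes its children, so the
        # reversed sequence yields children before parents.
        return reversed(list(self.preorder()))

    def leaves(self) -> Iterator[Vertex]:
        return (v for v in self.preorder() if v.is_leaf)

    def inner_vertices(self) -> Iterator[Vertex]:
        return (v for v in self.preorder() if not v.is_leaf)

    # -- basic queries -------------------------------------------------------

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(v.label for v in self.leaves())

    @property
    def n_vertices(self) -> int:
        return sum(1 for _ in self.preorder())

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    def is_phylogenetic(self) -> bool:
        """True iff every inner vertex has at least two children."""
        return all(len(v.children) != 1 for v in self.preorder())

    def is_binary(self) -> bool:
        return all(v.is_leaf or len(v.children) == 2 for v in self.preorder())

    def find(self, label: str) -> Vertex | None:
        """First vertex (preorder) carrying ``label``, or None."""
        for v in self.preorder():
            if v.label == label:
                return v
        return None

    # -- copying -------------------------------------------------------------

    def copy_with_map(self) -> tuple["RootedTree", dict[Vertex, Vertex]]:
        """Deep copy; returns the copy and the original->copy vertex map."""
        mapping: dict[Vertex, Vertex] = {}
        new_root = Vertex(self.root.label)
        mapping[self.root] = new_root
        stack = [self.root]
        while stack:
            v = stack.pop()
            nv = mapping[v]
            for c in v.children:
                nc = Vertex(c.label)
                nv.add_child(nc)
                mapping[c] = nc
                stack.append(c)
        return RootedTree(new_root), mapping

    def copy(self) -> "RootedTree":
        return self.copy_with_map()[0]

    # -- validation ----------------------------------------------------------

    def validate(self) -> None:
        """Check structural invariants; raise :class:`InputError` on failure.

        Verified: parent/children mutual consistency, leaf labelling, and
        uniqueness of leaf labels.
        """
        if self.root.parent is not None:
            raise InputError("root must not have a parent")
        seen_labels: set[str] = set()
        for v in self.preorder():
            for c in v.children:
                if c.parent is not v:
                    raise InputError("inconsistent parent/children links")
            if v.is_leaf:
                if v.label is None:
                    raise InputError("leaf without label")
                if v.label in seen_labels:
                    raise InputError(f"duplicate leaf label {v.label!r}")
                seen_labels.add(v.label)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<RootedTree with {self.n_leaves} leaves>"


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str, *, allow_unary: bool = False) -> RootedTree:
    """Parse a rooted Newick string into a :class:`RootedTree`.

    Branch lengths are tolerated and discarded; inner labels are preserved;
    the final semicolon is optional.  Unless ``allow_unary`` is set, trees
    with single-child vertices (non-phylogenetic trees) are rejected.

    Raises :class:`NewickError` on malformed input and :class:`InputError`
    on duplicate leaf labels or unary vertices.
    """
    s = text.strip()
    if not s:
        raise NewickError("empty Newick string")
    if not s.endswith(";"):
        s += ";"
    try:
        dtree = dendropy.Tree.get(
            data=s,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except (InputError, NewickError):
        raise
    except Exception as exc:
        raise NewickError(f"malformed Newick: {exc}") from exc

    def label_of(nd) -> str | None:
        if nd.taxon is not None:
            return nd.taxon.label
        return nd.label

    root = Vertex(label_of(dtree.seed_node))
    stack = [(dtree.seed_node, root)]
    while stack:
        nd, v = stack.pop()
        for c in nd.child_nodes():
            cv = Vertex(label_of(c))
            v.add_child(cv)
            stack.append((c, cv))
    tree = RootedTree(root)
    tree.validate()  # catches unlabeled or duplicate leaves
    if not allow_unary and not tree.is_phylogenetic():
        raise InputError(
            "tree is not phylogenetic (vertex with a single child); "
            "pass allow_unary=True to accept it anyway"
        )
    return tree


_TOKEN_SAFE = re.compile(r"^[A-Za-z0-9_.+|-]+$")


def _format_label(label: str) -> str:
    if _TOKEN_SAFE.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(tree: RootedTree) -> str:
    """Serialize to Newick (no branch lengths); inner labels are kept.

    The round trip ``parse_newick(write_newick(T))`` yields a tree with the
    same cluster system and the same labels as ``T``.
    """
    parts: dict[Vertex, str] = {}
    for v in tree.postorder():
        label = _format_label(v.label) if v.label is not None else ""
        if v.is_leaf:
            if v.label is None:
                raise InputError("leaf without label cannot be serialized")
            parts[v] = label
        else:
            parts[v] = "(" + ",".join(parts[c] for c in v.children) + ")" + label
    return parts[tree.root] + ";"


# ---------------------------------------------------------------------------
# Clusters and hierarchies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterSystem:
    """A set of clusters over a fixed ground set of leaf labels."""

    clusters: frozenset[Cluster]
    ground_set: frozenset[str]

    def __post_init__(self) -> None:
        for c in self.clusters:
            if not c:
                raise InputError("clusters must be non-empty")
            if not c <= self.ground_set:
                raise InputError("cluster not contained in the ground set")

    def __iter__(self):
        return iter(self.clusters)

    def __len__(self) -> int:
        return len(self.clusters)

    def __contains__(self, item) -> bool:
        return item in self.clusters

    def union(self, other: "ClusterSystem") -> "ClusterSystem":
        if self.ground_set != other.ground_set:
            raise InputError("cluster systems live on different ground sets")
        return ClusterSystem(self.clusters | other.clusters, self.ground_set)


def cluster_map(tree: RootedTree) -> dict[Vertex, Cluster]:
    """Map every vertex ``v`` to its cluster ``L(T(v))``."""
    cm: dict[Vertex, Cluster] = {}
    for v in tree.postorder():
        if v.is_leaf:
            cm[v] = frozenset((v.label,))
        else:
            cm[v] = frozenset(itertools.chain.from_iterable(cm[c] for c in v.children))
    return cm


def clusters(tree: RootedTree) -> ClusterSystem:
    """The cluster system ``H(T)``; one cluster per vertex for phylogenetic T."""
    cm = cluster_map(tree)
    return ClusterSystem(frozenset(cm.values()), tree.leaf_labels())


def is_hierarchy(cs: ClusterSystem) -> bool:
    """True iff ``cs`` is a hierarchy on its ground set.

    The three conditions: the ground set is a cluster, every two clusters are
    nested or disjoint, and every singleton is a cluster.  Nestedness is
    checked by a single sweep over the clusters in order of decreasing size,
    maintaining for each label the smallest cluster seen so far that contains
    it: a new cluster is compatible with everything so far iff all of its
    labels currently point to one and the same container.
    """
    H = cs.clusters
    L = cs.ground_set
    if L not in H:
        return False
    for x in L:
        if frozenset((x,)) not in H:
            return False
    owner: dict[str, Cluster] = {}
    for c in sorted(H, key=len, reverse=True):
        if c != L:
            owners = {owner[x] for x in c}
            if len(owners) != 1:
                return False
        for x in c:
            owner[x] = c
    return True


def tree_from_hierarchy(cs: ClusterSystem) -> RootedTree:
    """The unique rooted phylogenetic tree with cluster system ``cs``.

    This is the Hasse diagram of the clusters under set inclusion: each
    cluster's parent is its inclusion-minimal strict superset, found by the
    same decreasing-size sweep used in :func:`is_hierarchy`.  Serves as the
    brute-force construction behind the hierarchy/tree bijection.
    """
    if not is_hierarchy(cs):
        raise InputError("cluster system is not a hierarchy")
    order = sorted(cs.clusters, key=lambda c: (-len(c), tuple(sorted(c))))
    nodes: dict[Cluster, Vertex] = {}
    owner: dict[str, Cluster] = {}
    for c in order:
        v = Vertex(next(iter(c)) if len(c) == 1 else None)
        nodes[c] = v
        if c != cs.ground_set:
            parent_cluster = owner[next(iter(c))]
            nodes[parent_cluster].add_child(v)
        for x in c:
            owner[x] = c
    return RootedTree(nodes[cs.ground_set])


def isomorphic(t1: RootedTree, t2: RootedTree) -> bool:
    """Equality of trees on the same leaf set, as equality of cluster systems.

    For trees on a common leaf set this coincides with labelled rooted-tree
    isomorphism, because the cluster system determines the tree.
    """
    if t1.leaf_labels() != t2.leaf_labels():
        return False
    return clusters(t1).clusters == clusters(t2).clusters


# ---------------------------------------------------------------------------
# Last common ancestors and triples
# ---------------------------------------------------------------------------

def lca(tree: RootedTree, labels: Iterable[str]) -> Vertex:
    """Last common ancestor of a set of leaf labels (naive ancestor walks).

    The returned vertex carries the inclusion-minimal cluster containing the
    labels.  Intentionally naive -- this is a definitional oracle for tests,
    not a hot-path routine.
    """
    label_set = set(labels)
    if not label_set:
        raise InputError("lca of an empty label set is undefined")
    leaf_of = {v.label: v for v in tree.leaves()}
    missing = label_set - leaf_of.keys()
    if missing:
        raise InputError(f"labels not in tree: {sorted(missing)}")
    it = iter(label_set)
    cur = leaf_of[next(it)]
    for lbl in it:
        ancestors = set()
        w: Vertex | None = cur
        while w is not None:
            ancestors.add(w)
            w = w.parent
        w = leaf_of[lbl]
        while w not in ancestors:
            w = w.parent
        cur = w
    return cur


@dataclass(frozen=True)
class Triple:
    """A rooted triple ``xy|z``: x and y are closer to each other than to z."""

    cherry: frozenset
    outgroup: str

    def __post_init__(self) -> None:
        if len(self.cherry) != 2 or self.outgroup in self.cherry:
            raise InputError("triple needs three pairwise distinct labels")

    @classmethod
    def of(cls, x: str, y: str, z: str) -> "Triple":
        return cls(frozenset((x, y)), z)

    def __str__(self) -> str:
        x, y = sorted(self.cherry)
        return f"{x}{y}|{self.outgroup}"

    __repr__ = __str__


def triples(tree: RootedTree) -> set[Triple]:
    """All rooted triples displayed by a phylogenetic tree.

    ``xy|z`` is displayed iff some cluster contains x and y but not z;
    computed by brute force over all label triplets (oracle-grade).
    """
    cm = list(clusters(tree).clusters)
    labs = sorted(tree.leaf_labels())
    out: set[Triple] = set()
    for x, y in itertools.combinations(labs, 2):
        for z in labs:
            if z == x or z == y:
                continue
            if any(x in C and y in C and z not in C for C in cm):
                out.add(Triple.of(x, y, z))
    return out


# ---------------------------------------------------------------------------
# Display / refinement predicates and contraction
# ---------------------------------------------------------------------------

def displays_same_leafset(tree: RootedTree, other: RootedTree) -> bool:
    """True iff ``tree`` displays ``other`` (same leaf set).

    For trees on a common leaf set, display is equivalent to refinement:
    ``tree`` displays ``other`` iff ``H(other)`` is a subset of ``H(tree)``.
    """
    if tree.leaf_labels() != other.leaf_labels():
        raise InputError("trees must share the same leaf set")
    return clusters(other).clusters <= clusters(tree).clusters


def _splice(v: Vertex) -> None:
    """Contract the edge above ``v`` in place: reattach its children to the
    parent at v's position, preserving relative child order."""
    parent = v.parent
    idx = parent.children.index(v)
    for c in v.children:
        c.parent = parent
    parent.children[idx:idx + 1] = v.children
    v.parent = None
    v.children = []


def contract_edge(tree: RootedTree, child_vertex: Vertex) -> RootedTree:
    """Contract the inner edge above ``child_vertex``; returns a new tree.

    Removes exactly the cluster ``L(T(child_vertex))`` from the cluster
    system.  ``child_vertex`` must be an inner, non-root vertex of ``tree``.
    """
    if child_vertex.is_leaf or child_vertex.parent is None:
        raise InputError("can only contract the edge above an inner non-root vertex")
    new_tree, mapping = tree.copy_with_map()
    _splice(mapping[child_vertex])
    return new_tree
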