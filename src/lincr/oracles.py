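"""Independent reference algorithms used as correctness oracles.

Two classical routes to the common refinement exist besides the bottom-up
merge, and both are implemented here so that every verdict and every output
tree of :func:`lincr.merge.lincr` can be cross-checked:

* :func:`refine_by_union` -- the definitional route: pool all clusters,
  test the hierarchy property, and read the tree off the Hasse diagram.
* :func:`build` -- Aho et al.'s BUILD on rooted triples: the union of the
  inputs' triple sets is consistent iff a common refinement exists, and
  BUILD then returns exactly the least-resolved refinement.

Neither is tuned for speed; both are deliberately simple and structurally
unrelated to the merge they check.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .tree import (
    ClusterSystem,
    InputError,
    RootedTree,
    Triple,
    Vertex,
    clusters,
    is_hierarchy,
    tree_from_hierarchy,
)

__all__ = ["build", "refine_by_union", "representative_triples"]


def refine_by_union(trees: Sequence[RootedTree]) -> RootedTree | None:
    """Common refinement via the cluster-union definition, or None.

    Pools the cluster systems of all inputs; if the union is a hierarchy the
    unique tree with exactly those clusters is returned, otherwise None (no
    common refinement exists).
    """
    trees = list(trees)
    if not trees:
        raise InputError("need at least one input tree")
    ground = trees[0].leaf_labels()
    pooled: set = set()
    for t in trees:
        if t.leaf_labels() != ground:
            raise InputError("input trees must share one leaf-label set")
        pooled |= clusters(t).clusters
    cs = ClusterSystem(frozenset(pooled), ground)
    if not is_hierarchy(cs):
        return None
    return tree_from_hierarchy(cs)


def _components(labels: frozenset, triple_set: Iterable[Triple]) -> list[set]:
    """Connected components of the Aho graph on ``labels``.

    The graph has an edge {x, y} for every triple xy|z whose three labels
    all lie in ``labels``.  Union-find keeps the partition deterministic.
    """
    parent = {x: x for x in labels}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in triple_set:
        if t.outgroup in parent and t.cherry <= parent.keys():
            x, y = sorted(t.cherry)
            rx, ry = find(x), find(y)
            if rx != ry:
                parent[rx] = ry
    comps: dict = {}
    for x in labels:
        comps.setdefault(find(x), set()).add(x)
    return list(comps.values())


def build(triple_set: Iterable[Triple], labels: Iterable[str]) -> RootedTree | None:
    """Aho et al.'s BUILD: a tree on ``labels`` displaying every triple, or None.

    Recursion (here: explicit stack): partition the current label set into
    the connected components of the Aho graph; a single component on more
    than one label means the triples are inconsistent; singleton components
    become leaves.  The result is least resolved with respect to the input
    triples.
    """
    L = frozenset(labels)
    if not L:
        raise InputError("empty label set")
    triple_list = list(set(triple_set))
    for t in triple_list:
        if not (t.cherry <= L and t.outgroup in L):
            raise InputError(f"triple {t} uses labels outside the label set")
    root = Vertex()
    stack: list[tuple[Vertex, frozenset]] = [(root, L)]
    while stack:
        node, S = stack.pop()
        if len(S) == 1:
            node.label = next(iter(S))
            continue
        comps = _components(S, triple_list)
        if len(comps) == 1:
            return None  # Aho graph connected on >= 2 labels: inconsistent
        for comp in sorted(comps, key=min):
            child = Vertex()
            node.add_child(child)
            stack.append((child, frozenset(comp)))
    return RootedTree(root)


def representative_triples(tree: RootedTree) -> set[Triple]:
    """A small triple set whose BUILD closure reproduces the tree.

    For every inner non-root vertex v, one representative leaf is taken from
    each child subtree and consecutive representatives are paired into
    cherries against a representative of one of v's siblings.  This pins
    down the cluster of v with deg(v)-1 triples, so the whole set has O(|L|)
    triples; for binary trees its size equals the number of inner edges.
    The guarantee is closure-equivalence (``build`` on the result is
    isomorphic to ``tree``), not minimality.
    """
    rep: dict[Vertex, str] = {}
    for v in tree.postorder():
        rep[v] = v.label if v.is_leaf else rep[v.children[0]]
    out: set[Triple] = set()
    for v in tree.preorder():
        if v.is_leaf or v.parent is None:
            continue
        sibling = next(c for c in v.parent.children if c is not v)
        z = rep[sibling]
        for a, b in zip(v.children, v.children[1:]):
            out.add(Triple.of(rep[a], rep[b], z))
    return out
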