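"""Simulation of compatible (and incompatible) refinement instances.

The compatible-instance protocol: grow a random phylogenetic tree T* by
stepwise leaf attachment -- repeatedly pick a vertex uniformly at random;
if it is currently a leaf it receives two children, otherwise one new leaf
child, so the leaf count rises by exactly one per step and the tree stays
phylogenetic (though in general not binary).  Each of the k input trees is
then an independent copy of T* with every inner edge contracted
independently with probability p.  By construction T* refines every input,
so a common refinement exists -- but T* itself is generally *not* the
minimal one, so tests must compare algorithm output against the cluster
union, never against T*.

Incompatible instances are drawn by rejection: k independent random trees
are usually incompatible already; a deterministic fallback pair is used if
the retry budget runs out.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .tree import (
    ClusterSystem,
    InputError,
    RootedTree,
    Vertex,
    _splice,
    clusters,
    is_hierarchy,
    parse_newick,
)

__all__ = [
    "SimulationConfig",
    "contract_random_inner_edges",
    "make_incompatible_instance",
    "make_instance",
    "random_tree",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one compatible instance: leaf count n >= 2, number of
    derived trees k >= 1, inner-edge contraction probability p in [0, 1],
    and the RNG seed."""

    n_leaves: int
    k: int
    p_contract: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_leaves < 2:
            raise InputError("n_leaves must be >= 2")
        if self.k < 1:
            raise InputError("k must be >= 1")
        if not 0.0 <= self.p_contract <= 1.0:
            raise InputError("p_contract must lie in [0, 1]")


def random_tree(n_leaves: int, rng: random.Random) -> RootedTree:
    """Random phylogenetic tree by stepwise leaf attachment.

    The attachment vertex is chosen uniformly over the current vertex set.
    Leaves are labelled t1..tn in left-to-right order after growth.
    Deterministic given the RNG state.
    """
    if n_leaves < 2:
        raise InputError("n_leaves must be >= 2")
    root = Vertex()
    vertices = [root]
    leaves_now = 1  # the lone root counts as a leaf until it gains children
    while leaves_now < n_leaves:
        v = vertices[rng.randrange(len(vertices))]
        if v.is_leaf:
            c1, c2 = Vertex(), Vertex()
            v.add_child(c1)
            v.add_child(c2)
            vertices.extend((c1, c2))
        else:
            c = Vertex()
            v.add_child(c)
            vertices.append(c)
        leaves_now += 1
    tree = RootedTree(root)
    for idx, leaf in enumerate(tree.leaves(), start=1):
        leaf.label = f"t{idx}"
    return tree


def contract_random_inner_edges(
    tree: RootedTree, p: float, rng: random.Random
) -> RootedTree:
    """Independently contract each inner edge of a copy with probability p.

    Leaf edges are never touched (contracting one would change the leaf
    set).  The result is phylogenetic and is displayed by ``tree``.
    """
    if not 0.0 <= p <= 1.0:
        raise InputError("p must lie in [0, 1]")
    new_tree, _ = tree.copy_with_map()
    # Decide first, then splice top-down; splicing a parent re-parents its
    # children, so the preorder snapshot keeps every target valid.
    targets = [
        v for v in new_tree.preorder() if v.children and v.parent is not None
    ]
    for v in targets:
        if rng.random() < p:
            _splice(v)
    return new_tree


def make_instance(cfg: SimulationConfig) -> tuple[RootedTree, list[RootedTree]]:
    """One compatible instance: (T*, [T_1..T_k]) with T* refining every T_i."""
    rng = random.Random(cfg.seed)
    t_star = random_tree(cfg.n_leaves, rng)
    inputs = [
        contract_random_inner_edges(t_star, cfg.p_contract, rng)
        for _ in range(cfg.k)
    ]
    return t_star, inputs


def _fallback_incompatible(n_leaves: int, k: int) -> list[RootedTree]:
    labels = [f"t{i}" for i in range(1, n_leaves + 1)]
    rest = "".join("," + x for x in labels[3:])
    nw1 = f"(({labels[0]},{labels[1]}),{labels[2]}{rest});"
    nw2 = f"(({labels[0]},{labels[2]}),{labels[1]}{rest});"
    star = "(" + ",".join(labels) + ");"
    trees = [parse_newick(nw1), parse_newick(nw2)]
    trees.extend(parse_newick(star) for _ in range(k - 2))
    return trees


def make_incompatible_instance(
    n_leaves: int, k: int, rng: random.Random, *, max_retries: int = 64
) -> list[RootedTree]:
    """k trees on a common leaf set with no common refinement.

    Rejection sampling over independent random trees; after ``max_retries``
    failures a deterministic incompatible pair (clashing cherries, padded
    with star trees for k > 2) is returned instead.
    """
    if n_leaves < 3:
        raise InputError("need n_leaves >= 3 for an incompatible instance")
    if k < 2:
        raise InputError("need k >= 2 for an incompatible instance")
    ground = frozenset(f"t{i}" for i in range(1, n_leaves + 1))
    for _ in range(max_retries):
        trees = [random_tree(n_leaves, rng) for _ in range(k)]
        pooled: set = set()
        for t in trees:
            pooled |= clusters(t).clusters
        if not is_hierarchy(ClusterSystem(frozenset(pooled), ground)):
            return trees
    return _fallback_incompatible(n_leaves, k)
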