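"""Linear-time common refinement of rooted trees on a shared leaf set.

Given k rooted phylogenetic trees T_1..T_k on the same leaf set L, a common
refinement is a tree T whose cluster system is the union of the inputs',
H(T) = H(T_1) u ... u H(T_k).  It exists iff that union is a hierarchy, and
is then unique and least resolved.  This module constructs the candidate T
directly, in O(k|L|) time, by computing its parent function bottom-up, and
then verifies the candidate.

The construction identifies vertices across trees by their clusters without
ever materializing a cluster.  For each merged vertex v it maintains

* ``J(v)``   -- the indices of the input trees containing a vertex with
  cluster L(T(v)),
* ``p_i(v)`` -- for every tree i, the lowest vertex of T_i weakly above v
  (the last common ancestor in T_i of v's cluster), and
* per-tree leaf counts ``l_i(.)``, because among the pairwise comparable
  parent candidates of v, ancestor order coincides with cluster size.

Starting from the leaves (where all of this is trivial), the parent of each
processed vertex is the candidate of strictly minimal leaf count among
``parent_{T_i}(v)`` for i in J(v) and ``p_i(v)`` for i outside J(v); the set
of indices attaining the minimum is exactly J of the new parent, and the
``p_i`` maps of the parent follow by a constant-time-per-tree recursion.  A
FIFO queue with an ever-enqueued set drives the traversal; since a
phylogenetic tree on |L| leaves has at most 2|L|-1 vertices, more than
2|L|-2 distinct non-root vertices prove incompatibility immediately.

If the inputs are incompatible the parent function may still complete; a
two-stage verification (phylogenetic check, then a contraction-based display
check of every input against the candidate) makes the verdict sound.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

from .tree import InputError, RootedTree, Vertex, cluster_map

__all__ = [
    "FAILURE_REASONS",
    "IncompatibilityDetected",
    "MergeState",
    "RefinementResult",
    "compute_parent",
    "init_state",
    "leaf_counts",
    "lincr",
    "merge",
    "queue_trace",
    "update_pmaps",
    "verify_displays",
    "verify_phylogenetic",
]

FAILURE_REASONS = (
    "vertex_budget_exceeded",
    "parent_not_strictly_larger",
    "not_phylogenetic",
    "display_check_failed",
)


class IncompatibilityDetected(Exception):
    """Raised internally when the merge proves the inputs incompatible."""

    def __init__(self, reason: str) -> None:
        assert reason in FAILURE_REASONS
        self.reason = reason
        super().__init__(reason)


@dataclass
class MergeState:
    """Bookkeeping of the bottom-up merge.

    Tree indices are 0-based throughout.  ``pmap[v][i]`` is the vertex
    ``p_i(v)`` of tree i; for ``i in J[v]`` it is v's own representative in
    tree i.  ``corr[i]`` maps vertices of tree i back to merged vertices and
    is set exactly for the trees containing the merged vertex.  ``seen`` is
    the set of merged vertices ever enqueued (the root never enters it).
    """

    trees: list[RootedTree]
    leaf_count: list[dict[Vertex, int]]
    pmap: dict[Vertex, list[Vertex]] = field(default_factory=dict)
    J: dict[Vertex, set[int]] = field(default_factory=dict)
    corr: list[dict[Vertex, Vertex]] = field(default_factory=list)
    queue: deque = field(default_factory=deque)
    seen: set = field(default_factory=set)
    parent_out: dict[Vertex, Vertex] = field(default_factory=dict)
    root: Vertex | None = None
    n_leaves: int = 0

    @property
    def k(self) -> int:
        return len(self.trees)


@dataclass
class RefinementResult:
    """Outcome of the refinement: either the tree or an incompatibility verdict.

    On success, ``tree`` satisfies H(tree) = union of the inputs' cluster
    systems, and ``J_annotation`` maps each vertex to the (0-based) indices
    of the input trees whose cluster systems contain that vertex's cluster.
    """

    status: str  # "refined" | "incompatible"
    tree: RootedTree | None = None
    J_annotation: dict[Vertex, frozenset] | None = None
    failure_reason: str | None = None

    @property
    def refined(self) -> bool:
        return self.status == "refined"


class ParentCandidate(NamedTuple):
    """Minimal parent candidate: its leaf count and, for every tree index
    attaining the minimum, the candidate vertex within that tree."""

    ell: int
    by_tree: dict

    @property
    def J_new(self) -> frozenset:
        return frozenset(self.by_tree)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def leaf_counts(tree: RootedTree) -> dict[Vertex, int]:
    """Number of leaves below each vertex, in one post-order sweep."""
    ell: dict[Vertex, int] = {}
    for v in tree.postorder():
        ell[v] = 1 if v.is_leaf else sum(ell[c] for c in v.children)
    return ell


def _validate_inputs(trees: Sequence[RootedTree]) -> frozenset[str]:
    if len(trees) < 1:
        raise InputError("need at least one input tree")
    base = trees[0].leaf_labels()
    for idx, t in enumerate(trees):
        t.validate()
        if not t.is_phylogenetic():
            raise InputError(f"input tree {idx} is not phylogenetic")
        if t.leaf_labels() != base:
            raise InputError("input trees must share one leaf-label set")
    return base


def init_state(trees: Sequence[RootedTree]) -> MergeState:
    """Set up the merge: one merged vertex per leaf, J = all trees, queue full."""
    trees = list(trees)
    base = _validate_inputs(trees)
    k = len(trees)
    state = MergeState(trees=trees, leaf_count=[leaf_counts(t) for t in trees])
    state.corr = [dict() for _ in range(k)]
    state.n_leaves = len(base)
    leaf_of = [{v.label: v for v in t.leaves()} for t in trees]
    for leaf in trees[0].leaves():
        m = Vertex(leaf.label)
        state.J[m] = set(range(k))
        state.pmap[m] = [leaf_of[i][leaf.label] for i in range(k)]
        for i in range(k):
            state.corr[i][leaf_of[i][leaf.label]] = m
        state.queue.append(m)
        state.seen.add(m)
    return state


def compute_parent(v: Vertex, state: MergeState) -> ParentCandidate | None:
    """Parent candidate of merged vertex ``v`` by the minimum-cardinality rule.

    The candidate set is ``parent_{T_i}(v)`` for i in J(v) and ``p_i(v)``
    for i outside J(v); all candidates are weakly above v in the prospective
    tree and pairwise comparable, so the strictly smallest leaf count picks
    the parent and the indices attaining it form J of the parent.

    Returns None (root signal) iff v has no parent in a tree containing it.
    Raises :class:`IncompatibilityDetected` if no candidate is strictly
    larger than v -- impossible for compatible inputs.
    """
    Jv = state.J[v]
    pv = state.pmap[v]
    i0 = next(iter(Jv))
    ell_v = state.leaf_count[i0][pv[i0]]
    best_ell: int | None = None
    by_tree: dict[int, Vertex] = {}
    for i in range(state.k):
        if i in Jv:
            cand = pv[i].parent
            if cand is None:
                return None  # v is the root of T_i, hence the root of T
        else:
            cand = pv[i]
        ell = state.leaf_count[i][cand]
        if best_ell is None or ell < best_ell:
            best_ell = ell
            by_tree = {i: cand}
        elif ell == best_ell:
            by_tree[i] = cand
    if best_ell <= ell_v:
        raise IncompatibilityDetected("parent_not_strictly_larger")
    return ParentCandidate(best_ell, by_tree)


def update_pmaps(u: Vertex, v: Vertex, state: MergeState) -> None:
    """Fill ``p_i(u)`` for the freshly created parent u of v.

    Three cases per tree i: u's own representative if i in J(u); the parent
    of v in T_i if i in J(v); otherwise u inherits ``p_i(v)``.  The cases
    overlap but agree wherever they do.
    """
    Ju = state.J[u]
    Jv = state.J[v]
    pv = state.pmap[v]
    pu: list[Vertex] = []
    for i in range(state.k):
        if i in Ju:
            pu.append(pv[i].parent if i in Jv else pv[i])
        elif i in Jv:
            pu.append(pv[i].parent)
        else:
            pu.append(pv[i])
    state.pmap[u] = pu


def merge(trees: Sequence[RootedTree]) -> MergeState:
    """Run the bottom-up construction of the parent function.

    Processes a FIFO queue seeded with the leaves.  For each dequeued vertex
    the parent candidate is computed; an existing merged vertex is recognized
    through the correspondence pointers, otherwise a new one is created (and
    enqueued, unless it is the root -- recognizable because its in-tree
    representative is a tree root).  Creating more than 2|L|-2 distinct
    non-root vertices proves incompatibility and aborts.

    Returns the completed :class:`MergeState`; raises
    :class:`IncompatibilityDetected` on an early negative verdict.
    """
    state = init_state(trees)
    budget = 2 * state.n_leaves - 2
    while state.queue:
        v = state.queue.popleft()
        pc = compute_parent(v, state)
        if pc is None:
            state.root = v
            continue
        u: Vertex | None = None
        for i, cand in pc.by_tree.items():
            u = state.corr[i].get(cand)
            if u is not None:
                break
        if u is None:
            u = Vertex()
            state.J[u] = set(pc.by_tree)
            for i, cand in pc.by_tree.items():
                state.corr[i][cand] = u
            update_pmaps(u, v, state)
            if any(cand.parent is None for cand in pc.by_tree.values()):
                # u's representatives are tree roots: u is the root of T.
                state.root = u
            else:
                state.seen.add(u)
                if len(state.seen) > budget:
                    raise IncompatibilityDetected("vertex_budget_exceeded")
                state.queue.append(u)
        state.parent_out[v] = u
        u.children.append(v)
        v.parent = u
    if state.root is None:  # pragma: no cover - defensive
        raise IncompatibilityDetected("parent_not_strictly_larger")
    return state


# ---------------------------------------------------------------------------
# verification
# ---------------------------------------------------------------------------

def verify_phylogenetic(tree: RootedTree) -> bool:
    """True iff no inner vertex has exactly one child (top-down, early exit)."""
    for v in tree.preorder():
        if len(v.children) == 1:
            return False
    return True


def verify_displays(
    tree: RootedTree,
    ti: RootedTree,
    i: int,
    J: dict[Vertex, set],
    corr_i: dict[Vertex, Vertex],
) -> bool:
    """Check that the candidate refinement displays input tree ``ti``.

    Conceptually: contract, in a copy of the candidate, every edge whose
    child vertex is not in tree i (i.e. lacks i in J), and verify that the
    contracted tree equals ``ti`` vertex by vertex under the maintained
    correspondence.  Implemented as a virtual contraction: for each vertex
    of ``ti``, its children (mapped into the candidate) must equal the
    nearest descendants of its counterpart that carry index i.  O(|L|).
    """
    if corr_i.get(ti.root) is not tree.root:
        return False
    for v in ti.preorder():
        m = corr_i.get(v)
        if m is None:
            return False
        if v.children:
            expected = set()
            for c in v.children:
                mc = corr_i.get(c)
                if mc is None:
                    return False
                expected.add(mc)
            surviving = set()
            stack = list(m.children)
            while stack:
                c = stack.pop()
                if i in J[c]:
                    surviving.add(c)
                else:
                    stack.extend(c.children)
            if surviving != expected:
                return False
    return True


# ---------------------------------------------------------------------------
# the full pipeline
# ---------------------------------------------------------------------------

def _binary_shortcut(trees: list[RootedTree]) -> RefinementResult | None:
    """Fast path when some input is already binary (maximally resolved).

    A binary input admits no further refinement, so it is the only possible
    candidate: the answer is positive iff every other input's clusters are
    contained in its cluster system.  Returns None when no input is binary.
    """
    from .tree import clusters  # local import to avoid cycle at module load

    bi = next(
        (idx for idx, t in enumerate(trees) if t.n_vertices == 2 * t.n_leaves - 1),
        None,
    )
    if bi is None:
        return None
    ref_clusters = clusters(trees[bi]).clusters
    for idx, t in enumerate(trees):
        if idx != bi and not clusters(t).clusters <= ref_clusters:
            return RefinementResult("incompatible", failure_reason="display_check_failed")
    out = trees[bi].copy()
    cm_out = cluster_map(out)
    by_cluster = {c: v for v, c in cm_out.items()}
    ann: dict[Vertex, set] = {v: set() for v in by_cluster.values()}
    for idx, t in enumerate(trees):
        for c in cluster_map(t).values():
            ann[by_cluster[c]].add(idx)
    return RefinementResult(
        "refined", tree=out, J_annotation={v: frozenset(s) for v, s in ann.items()}
    )


def lincr(
    trees: Sequence[RootedTree],
    *,
    verify: bool = True,
    binary_shortcut: bool = False,
) -> RefinementResult:
    """Decide whether the input trees have a common refinement and build it.

    Full pipeline: bottom-up merge, then the phylogenetic check and the
    per-input display check.  ``verify=False`` skips verification and is
    only safe when the inputs are known to be compatible (the merge's own
    early exits still fire).  ``binary_shortcut`` enables the optional fast
    path for binary inputs; it changes nothing about the result.

    Raises :class:`InputError` on malformed input (leaf-set mismatch,
    non-phylogenetic tree, duplicate labels); incompatibility is reported in
    the returned :class:`RefinementResult`, never raised.
    """
    trees = list(trees)
    _validate_inputs(trees)
    if len(trees) == 1:
        out = trees[0].copy()
        ann = {v: frozenset((0,)) for v in out.preorder()}
        return RefinementResult("refined", tree=out, J_annotation=ann)
    if binary_shortcut:
        res = _binary_shortcut(trees)
        if res is not None:
            return res
    try:
        state = merge(trees)
    except IncompatibilityDetected as exc:
        return RefinementResult("incompatible", failure_reason=exc.reason)
    out = RootedTree(state.root)
    if verify:
        # The parent function must define a single tree covering every
        # vertex ever created; a lost subtree or unary vertex means the
        # "tree" the parent function specifies is not phylogenetic.
        expected = len(state.seen) + (0 if state.root in state.seen else 1)
        reachable = sum(1 for _ in out.preorder())
        if reachable != expected or not verify_phylogenetic(out):
            return RefinementResult("incompatible", failure_reason="not_phylogenetic")
        for i in range(len(trees)):
            if not verify_displays(out, trees[i], i, state.J, state.corr[i]):
                return RefinementResult(
                    "incompatible", failure_reason="display_check_failed"
                )
    ann = {v: frozenset(state.J[v]) for v in out.preorder()}
    return RefinementResult("refined", tree=out, J_annotation=ann)


# ---------------------------------------------------------------------------
# queue-discipline illustration
# ---------------------------------------------------------------------------

def queue_trace(tree: RootedTree, *, use_seen_set: bool = True) -> Counter:
    """Replay the bottom-up queue discipline on a single tree, counting
    how often each vertex is enqueued.

    Demonstrates why the merge must remember every vertex *ever* enqueued:
    checking only current queue membership (``use_seen_set=False``) lets a
    vertex re-enter the queue after it was dequeued.  On the tree
    ``(a,(b,c)v1)v2`` with initial queue (a, b, c), the root v2 is enqueued
    twice without the seen set and exactly once with it.
    """
    counts: Counter = Counter()
    q: deque = deque()
    in_queue: Counter = Counter()
    seen: set = set()
    for leaf in tree.leaves():
        q.append(leaf)
        counts[leaf] += 1
        in_queue[leaf] += 1
        seen.add(leaf)
    while q:
        v = q.popleft()
        in_queue[v] -= 1
        u = v.parent
        if u is None:
            continue
        if use_seen_set:
            if u in seen:
                continue
            seen.add(u)
        elif in_queue[u] > 0:
            continue
        q.append(u)
        counts[u] += 1
        in_queue[u] += 1
    return counts
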