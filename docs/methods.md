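# Methods

## Problem and model

A rooted phylogenetic tree on a leaf set L is equivalent to its cluster
system H(T) = { L(T(v)) : v ∈ V(T) }, a hierarchy on L (the ground set and
all singletons are present; any two clusters are nested or disjoint), and
the map T ↦ H(T) is a bijection whose inverse is the Hasse diagram of the
clusters under inclusion.  For inputs T₁,…,T_k on a common leaf set, a
common refinement — a tree displaying all inputs — exists iff
⋃ᵢ H(Tᵢ) is a hierarchy; the minimal such tree is unique, satisfies
H(T) = ⋃ᵢ H(Tᵢ), and is least resolved (every edge contraction loses an
input cluster).  Equivalently, by the triple calculus, compatibility holds
iff the union of the inputs' rooted-triple sets is consistent, and BUILD on
that union returns exactly the minimal refinement.  These two equivalences
give the package its two independent oracles.

## The bottom-up merge

The main routine builds parent_T directly, in O(k·|L|):

* **State.**  For each merged vertex v: J(v), the indices of the inputs
  containing a vertex with v's cluster, and p_i(v), the lowest vertex of
  T_i weakly above v (p_i(v) = v's own representative iff i ∈ J(v)).  Leaf
  counts ℓ_i(·) per input tree are precomputed in one post-order sweep.
  Correspondence tables map input-tree vertices to merged vertices, set
  exactly for i ∈ J(v); vertex identity is object identity, so the tables
  are unambiguous.
* **Parent rule.**  The parent of v is the strictly smallest element of
  {parent_{T_i}(v) : i ∈ J(v)} ∪ {p_i(v) : i ∉ J(v)} under ancestor order.
  All candidates are pairwise comparable ancestors of v, so ancestor order
  coincides with leaf count and the minimum takes O(k) integer
  comparisons.  The indices attaining the minimum are exactly J of the new
  parent; its p-maps follow from a three-case constant-time-per-tree
  recursion (own representative / parent of v in T_i / inherited p_i(v)).
* **Queue discipline.**  A FIFO queue is seeded with the leaves (in the
  first input's leaf order — the result is order-independent, FIFO is for
  reproducibility).  A parent is enqueued only if it was never enqueued
  before; membership in the current queue is not enough, because a vertex
  can reappear as a parent after it was dequeued.  `merge.queue_trace`
  replays this discipline on a single tree and exhibits the failure mode
  (the root of `(a,(b,c)v1)v2` is enqueued twice without the ever-enqueued
  set).
* **Root handling.**  A merged vertex whose in-tree representative is a
  tree root is the global root (all input roots share the cluster L); it is
  recognized at creation and never enqueued, so the ever-enqueued set
  counts only non-root vertices.
* **Early exits.**  Two structural exits fire during the merge: a parent
  candidate not strictly larger than its child (impossible for compatible
  inputs), and more than 2|L|−2 distinct non-root vertices (a phylogenetic
  tree on |L| leaves has at most |L|−1 inner vertices, with equality for
  binary trees).  Each exit carries a machine-readable reason code.

### Verification

Equal-cardinality candidates are *identified* during the merge; on
incompatible inputs this identification can be wrong, so the verdict is
made sound afterwards: (1) the parent function must define a single
phylogenetic tree covering every created vertex (a lost subtree after
conflicting root assignments and a unary vertex both surface here, reason
`not_phylogenetic`); (2) for every input T_i, contracting in the candidate
every edge whose child lacks i in J must reproduce T_i vertex-by-vertex
under the maintained correspondence.  The contraction is virtual: for each
vertex of T_i, its mapped children are compared against the nearest
J-carrying descendants of its counterpart — O(|L|) per input, no copy.
Verification always runs by default; `verify=False` (CLI:
`--trust-compatible`) skips stage (2) and is safe only for inputs known to
be compatible.

An optional fast path (`binary_shortcut=True`, off by default) handles the
case that some input is already binary and hence maximally resolved: the
answer is positive iff every other input's clusters are contained in that
input's cluster system, and the J-annotation is then filled by cluster
matching.  It changes no result and is tested for equivalence against the
default path.

## Oracles

* `refine_by_union`: pools all clusters, tests the hierarchy property, and
  reads the tree off the Hasse diagram.  The hierarchy test is a single
  sweep over clusters in order of decreasing size, keeping for each label
  its current minimal container; a cluster is compatible with everything
  processed so far iff all its labels point to one container.  The test
  suite cross-checks this sweep against a brute-force pairwise-intersection
  test on random cluster families.
* `build`: Aho's recursive partition into connected components of the
  graph with an edge {x,y} per triple xy|z inside the current label set;
  one component on ≥ 2 labels means inconsistency.  Union-find with sorted
  tie-breaking keeps the construction deterministic; the graph is rebuilt
  per recursion level (quadratic, acceptable for an oracle).
* `representative_triples`: a compact encoding used to exercise BUILD —
  for each inner non-root vertex, consecutive child representatives are
  paired into cherries against one sibling representative, giving O(|L|)
  triples whose BUILD closure reproduces the tree (tested by round-trip);
  for binary trees the count equals the number of inner edges.  Minimality
  of the set is not claimed.

## Simulator

`make_instance` emulates the standard benchmark protocol: a random
phylogenetic tree T* grows by stepwise leaf attachment — a vertex is drawn
uniformly from the current vertex set; a leaf gains two children, an inner
vertex one — so the leaf count rises by one per step and T* is
phylogenetic but in general not binary.  The distribution of the
attachment vertex is not canonical; uniform over all vertices is the
natural choice and is fixed here.  Each of the k inputs contracts every
inner edge of a copy of T* independently with probability
p ∈ {0.1, 0.5, 0.9} (defaults exercised by the test grid with
k ∈ {2, 8}); leaf edges are never contracted, as that would change L.
T* refines every input, so instances are compatible by construction — but
T* is generally *not* the minimal refinement, so all tests compare against
the cluster union, never against T*.  Incompatible instances come from
rejection sampling over independent random trees with a deterministic
clashing-cherry fallback.

What the simulator does **not** emulate: branch lengths, non-uniform tree
shapes (Yule/coalescent), label-dependent error, or rogue taxa.  Passing
tests therefore certify the combinatorial contracts of the algorithms on
phylogenetic-tree inputs, not robustness to real-world reconstruction
artifacts.

## Numerical and design choices

* All randomness flows through explicitly seeded `random.Random`
  generators; same seed, same instance, byte-identical CLI output.
* Newick dialect: branch lengths parsed and discarded, inner labels kept,
  final semicolon optional on input and always written on output; unary
  vertices rejected unless explicitly allowed.  Parsing is delegated to
  dendropy; serialization is a bottom-up string assembly.
* Child order is preserved but semantically irrelevant: tree equality is
  equality of cluster systems, which is valid as labelled-isomorphism on a
  common leaf set.
* Tree indices are 0-based in the API; the CLI prints 1-based indices in
  `--annotate-sources` labels (joined with `+`).
* Degenerate inputs: k = 1 returns a copy of the input; a single shared
  leaf is handled (the leaf is the root); an empty tree list, mismatched
  leaf sets, duplicate labels and non-phylogenetic inputs raise
  `InputError`.
* Problem sizes in the test and acceptance suites: exhaustive catalogues
  up to 5 leaves (236 trees, 55 696 ordered pairs), random instances with
  up to 50 leaves and k ≤ 8 for the oracle comparisons, 100–500 draws per
  simulator property, and 600 → 1200 leaves for the scaling smoke test,
  which asserts only that the median runtime at most ~2.5× when |L|
  doubles.  These sizes make every contract checkable in seconds while
  covering the regimes where the algorithms differ.

## Known limitations

* The incompatibility *reason code* is implementation-defined: the same
  incompatible instance may be reported through different early exits
  depending on traversal order; only the verdict itself is guaranteed.
* No support for differing leaf sets (the general supertree problem), for
  nested-taxa labels, or for extracting maximum consistent triple subsets
  on incompatible inputs (NP-hard).
* `lca` and `triples` are deliberately naive oracles (quadratic/cubic) and
  are not meant for large trees.
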