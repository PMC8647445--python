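# lincr — common refinement of rooted phylogenetic trees

`lincr` decides whether k rooted phylogenetic trees T₁,…,T_k on one and the
same leaf set L are compatible — whether a single tree *displays* all of
them — and, if so, constructs their unique minimal **common refinement**:
the tree T whose cluster system is exactly the union of the inputs',

    H(T) = H(T₁) ∪ H(T₂) ∪ … ∪ H(T_k),

where H(T) = { L(T(v)) : v ∈ V(T) } is the set of leaf-label sets of the
subtrees of T.  Such a T exists iff the union is a *hierarchy* (any two
pooled clusters are nested or disjoint), and it is then unique and least
resolved: contracting any edge of T loses a cluster contributed by some
input.

The situation arises whenever partially resolved trees for the same taxa
come from different methods or data types — e.g. gene trees inferred from
best-match data on the one hand and from horizontal-transfer signals on the
other — and one wants to know whether they tell a single consistent story,
and what that story is.

## The algorithm

The core routine runs in O(k·|L|) time and builds the parent function of
the candidate refinement bottom-up, without ever materializing a cluster:

* vertices of different inputs are identified whenever their clusters
  coincide; per merged vertex v the algorithm tracks J(v), the set of input
  trees containing v, and p_i(v), the lowest vertex of T_i weakly above v;
* the parent of v is the candidate with strictly smallest leaf count among
  parent_{T_i}(v) for i ∈ J(v) and p_i(v) for i ∉ J(v) — legitimate because
  among these pairwise comparable candidates, ancestor order and cluster
  size agree — and the indices attaining the minimum are exactly J of the
  parent;
* a FIFO queue seeded with the leaves drives the traversal; a vertex is
  enqueued only if it was never enqueued before, and more than 2|L|−2
  distinct non-root vertices prove incompatibility outright;
* a two-stage verification (no unary vertices; every input is reproduced
  when the candidate is contracted down to it) makes the verdict sound even
  for incompatible inputs.

Two independent oracles cross-check every result: the definitional route
(pool clusters, test the hierarchy property, read the tree off the Hasse
diagram) and Aho's BUILD applied to the union of the inputs' rooted-triple
sets.  A simulator generates compatible instances by growing a random
phylogenetic tree and contracting inner edges independently with
probability p in k copies.

## Worked example

Simulate a compatible instance (8 leaves, 3 trees, contraction probability
0.5) and refine it:

```sh
$ lincr simulate -n 8 -k 3 -p 0.5 --seed 11 --outdir sim
$ cat sim/input_1.nwk sim/input_2.nwk sim/input_3.nwk
(t1,(t2,t3,t4,t5,t6),t7,t8);
(t1,t2,t3,t4,(t5,t6),t7,t8);
(t1,((t2,t3,t4,(t5,t6)),t7,t8));
$ lincr refine sim/input_*.nwk --annotate-sources
(t1,(t7,t8,(t2,t3,t4,(t5,t6)2+3)1+3)3)1+2+3;
```

The three partially resolved inputs merge into one tree; each inner label
lists which input trees contain that vertex's cluster (1-based): the cherry
{t5,t6} comes from inputs 2 and 3, the cluster {t2,…,t6} from inputs 1 and
3, and {t2,…,t8} only from input 3.  Incompatible inputs exit with status 1
and a reason code on stderr:

```sh
$ printf '((a,b),c);\n' > x.nwk; printf '((a,c),b);\n' > y.nwk
$ lincr refine x.nwk y.nwk; echo "exit $?"
incompatible: not_phylogenetic
exit 1
```

The same functionality is available as a library:

```python
>>> from lincr import parse_newick, lincr, write_newick
>>> r = lincr([parse_newick("((a,b),c,d);"), parse_newick("(a,b,(c,d));")])
>>> r.status, write_newick(r.tree)
('refined', '((a,b),(c,d));')
```

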