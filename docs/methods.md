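# Methods

## Problem and algorithm

The package completes an unrooted binary gene tree *t* on taxa *R* to the
full taxon set *S* of an unrooted binary reference tree *T*, minimizing the
Robinson–Foulds (RF) distance to *T* over all completions (trees *T′* on
*S* with *T′*|_R = *t*).  RF is computed over nontrivial bipartitions only;
for two binary trees on one leaf set it equals twice the number of splits
unique to either tree.

The solver is greedy leaf insertion.  For each missing taxon *x* (default:
lexicographic order over *S* ∖ *R*), the reference is restricted to the
current taxa plus *x*, rooted at *x*, and *x* and its edge are removed,
giving a rooted binary tree on the current taxa.  A depth-first walk from
the root stops at the first *shared* edge — one whose clade forms a split
present in the current gene tree; leaf-incident edges are always shared, so
the walk always terminates.  The paired gene-tree edge is subdivided and
*x* attached to the new node.  The result is binary and restricts back to
the input gene tree by construction.

Optimality is certified, not assumed.  Deleting from *T* the *backbone*
(edges on paths between taxa of *R*) detaches rooted pendant groups of
missing taxa, the *superleaves*.  A superleaf is Type I when the split of
*R* at its attachment point occurs in the gene tree (it can be inserted at
zero RF cost) and Type II otherwise (any placement costs exactly +2: one
new unique split in each tree).  With *r* = RF(*T*|_R, *t*) and *m* the
Type II count, every completion satisfies RF(*T*, *T′*) ≥ *r* + 2*m*; the
greedy tree achieves equality, and `CompletionReport` carries both sides of
that identity so every run is self-checking.  Multiple optimal completions
generally exist; one is returned, with the insertion log documenting the
choices made.

## Implementation notes

* **Shared-edge classification.**  Edges are classified by computing each
  tree's clade sets once (depth-first) and using canonical bipartitions as
  hash keys, so each edge's status and its paired edge are O(1) expected
  lookups and the whole classification is quadratic in the leaf count.
  This replaces an explicit LCA-matrix formulation with identical output
  and the same asymptotics.  A slower per-edge scanning route
  (`classify_edges(..., method="direct")`) is kept as a self-check.
* **Recompute-per-insertion.**  Each insertion rebuilds the restriction and
  classification rather than patching them incrementally.  This is
  O(n²) per leaf (O(n³) worst case overall) instead of the achievable
  O(n²) total, but at the problem sizes the package targets (hundreds of
  taxa) completion is effectively instantaneous, the code is far simpler,
  and the per-step classification doubles as a direct audit of shared-edge
  preservation, which the test suite exploits.
* **Determinism.**  All traversals and serializations order children by
  smallest descendant leaf label; Newick output is canonical (trifurcation
  at the internal node adjacent to the smallest leaf), so topologically
  equal trees print identically.  Every stochastic routine takes a seed or
  a NumPy `Generator`.
* **Degenerate inputs.**  Gene trees need at least 3 leaves (RF over
  nontrivial splits is undefined below that); multifurcating inputs are
  rejected rather than refined; gene-tree taxa absent from the reference
  are an error rather than being silently pruned.  Branch lengths are
  parsed and can be re-emitted but are never used by any algorithm; edges
  created during completion carry no length, and completed trees are
  written topology-only by default.
* **Distances.**  Quartet distance is exact brute force over all C(n, 4)
  leaf subsets with splits held as bitmasks (adequate to a few hundred
  taxa); fast sublinear quartet algorithms are out of scope.  Matching
  distance builds the complete bipartite graph over the two nontrivial
  split sets with pair weight min(|A Δ C|, |A Δ D|) — the orientation-free
  count of leaves that must move — and solves it exactly with the Hungarian
  method (`scipy.optimize.linear_sum_assignment`).  Only nontrivial splits
  enter the matching, and no normalization is defined for it, so only the
  raw value is reported.

## Synthetic data

The generator emulates a multi-locus study with missing data:

* **Species trees** are uniform random binary topologies (sequential
  attachment of each leaf to a uniformly chosen edge, equivalent to random
  resolution of a star tree).
* **Gene-tree discordance** is produced by random NNI walks from the
  species tree, stopped when the normalized RF first reaches the target
  "AD" level (the mean normalized RF between gene trees and the species
  tree, the usual summary of incomplete-lineage-sorting severity) or a
  move cap of 50·n.  A single gene overshoots the target by at most one
  NNI step (2 / (2(n−3)) normalized), so the mean over genes tracks the
  target to within a few hundredths.  This controls the one statistic that
  matters to completion accuracy, but it is *not* a coalescent process: it
  produces no branch lengths, no deep-coalescence signature, and no
  correlation structure among loci.  A `gene_sampler` hook accepts a
  user-supplied generator (e.g. one backed by a coalescent simulator).
* **Missing data** follows a clade-multiset deletion protocol: the species
  tree is rooted at a designated outgroup; the sizes of its non-trivial
  clades (internal nodes below the root) form a multiset; each gene
  selected to be incomplete (default fraction 0.75) loses *k* taxa with
  *k* drawn uniformly from that multiset and taxa drawn uniformly without
  replacement.  Draws leaving fewer than 3 taxa are redrawn, since the
  completion machinery needs |R| ≥ 3 — a documented choice for an edge
  case the protocol itself does not address.
* **Defaults** (26 taxa of which one outgroup, 200 genes, target AD 0.10,
  75% of genes incomplete) describe a moderate-discordance condition at
  desk scale; AD targets of roughly 0.36 and 0.75 correspond to high and
  very high discordance.
* **Reference trees** for the self-contained pipeline come from the greedy
  (extended majority-rule) consensus of the complete gene trees: splits
  ranked by frequency (ties broken by canonical split order) and accepted
  greedily under pairwise compatibility.  The consensus may be
  multifurcating, while completion requires a binary reference, so the
  pipeline refines it with `resolve_polytomies` (seeded uniform random
  refinement of each polytomy) before use.

Passing tests on these data show that the algorithm is exactly optimal for
its objective and behaves sensibly as discordance and missingness vary;
they do not show that RF-optimal completion against an estimated species
tree recovers the true gene tree on real data, where gene-tree estimation
error and non-ILS processes also intervene.

## Validation design

The test suite certifies the implementation three independent ways: (i)
exhaustive enumeration of all completions on 200 random instances with up
to 8 taxa (the greedy optimum equals the true minimum in every case), (ii)
the r + 2m identity on 500 random instances with up to 50 taxa, with
per-insertion shared-edge preservation and per-superleaf topology
preservation audited on the same runs, and (iii) invariance of the
achieved optimum under 20 random insertion orders per instance.  RF values
are cross-checked against dendropy's symmetric difference, and the quartet
distance against an independent restriction-based oracle.  A simulated
26-taxon / 200-gene pipeline (greedy-consensus reference, moderate
discordance) checks the end-to-end ordering that completion against an
estimated reference beats uniform random attachment.

## Limitations

* Inputs must be binary; collapsing or refining weakly supported branches
  is not provided.
* The optimum is reported as a single tree; the (possibly large) set of
  co-optimal completions is not enumerated or summarized.
* The RF objective is unweighted; branch-length-, support-, quartet- or
  geodesic-weighted variants of the completion objective are not
  implemented.
* The discordance generator matches only the mean normalized RF level of a
  coalescent process, not its finer structure.
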