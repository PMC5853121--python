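"""Synthetic benchmark instances: random trees, discordant gene trees, and
the clade-multiset taxon-deletion protocol.

The generator emulates a multi-locus phylogenomic study: a species tree on
n taxa (one designated outgroup), a set of gene trees whose topological
discordance from the species tree is tuned to a target mean normalized RF
level ("AD", the standard proxy for the amount of incomplete lineage
sorting), and missing data produced by deleting taxa from a random subset
of the genes.  The number of taxa deleted from each affected gene is drawn
from the multiset of non-trivial clade sizes of the rooted species tree, so
the amount of missingness reflects the shape of the species tree itself.

Discordance is injected with random NNI walks rather than coalescent
simulation: only the realized AD level matters to the completion algorithm
downstream, and NNI walks give direct control over it.  A user-supplied
gene-tree sampler can be plugged in instead.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .errors import LeafSetError, TreeValidationError
from .tree import (
    Bipartition,
    UnrootedTree,
    bipartitions,
    normalized_rf,
    restrict,
    root_at_leaf_and_prune,
)

__all__ = [
    "SimulationConfig",
    "random_binary_tree",
    "nni_move",
    "perturb_to_ad",
    "clade_size_multiset",
    "deletion_protocol",
    "greedy_consensus",
    "tree_from_bipartitions",
    "resolve_polytomies",
    "simulate_dataset",
    "default_labels",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def default_labels(n_taxa: int, outgroup: str = "outgroup") -> List[str]:
    return [outgroup] + [f"t{i:02d}" for i in range(1, n_taxa)]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror a 26-taxon, 200-gene design: three quarters of the
    genes are incomplete, and the gene-tree discordance target is a
    moderate AD of 0.10 (mean normalized RF between gene trees and the
    species tree).
    """

    n_taxa: int = 26
    n_genes: int = 200
    target_ad: float = 0.10
    fraction_incomplete: float = 0.75
    seed: int = 0
    outgroup: str = "outgroup"

    def __post_init__(self):
        if not 0.0 <= self.target_ad <= 1.0:
            raise ValueError("target_ad must be in [0, 1]")
        if not 0.0 <= self.fraction_incomplete <= 1.0:
            raise ValueError("fraction_incomplete must be in [0, 1]")
        if self.n_taxa < 4:
            raise ValueError("need at least 4 taxa")

    @property
    def labels(self) -> List[str]:
        return default_labels(self.n_taxa, self.outgroup)


def random_binary_tree(labels: Sequence[str], seed=None) -> UnrootedTree:
    """Uniform random unrooted binary topology on the given labels.

    Leaves are attached sequentially to a uniformly chosen edge of the
    growing tree, which makes all (2n-5)!! labelled topologies
    equiprobable — the same law as resolving a star tree at random.
    """
    labels = list(labels)
    if len(labels) < 3:
        raise TreeValidationError("random tree needs at least 3 labels")
    if len(set(labels)) != len(labels):
        raise TreeValidationError("labels must be unique")
    rng = _as_rng(seed)
    tree = UnrootedTree()
    a = tree._new_node(labels[0])
    b = tree._new_node(labels[1])
    tree._add_edge(a, b)
    for lab in labels[2:]:
        edges = tree.edges()
        u, v = edges[rng.integers(len(edges))]
        tree.add_leaf_on_edge(u, v, lab)
    return tree


def nni_move(tree: UnrootedTree, seed=None) -> UnrootedTree:
    """One random nearest-neighbour-interchange across a random internal edge."""
    rng = _as_rng(seed)
    internal = [
        (u, v) for u, v in tree.edges()
        if not tree.is_leaf(u) and not tree.is_leaf(v)
    ]
    if not internal:
        raise TreeValidationError("tree has no internal edge to rearrange")
    u, v = internal[rng.integers(len(internal))]
    out = tree.copy()
    side_u = sorted(out.neighbors(u) - {v})
    side_v = sorted(out.neighbors(v) - {u})
    a = side_u[rng.integers(len(side_u))]
    b = side_v[rng.integers(len(side_v))]
    out._remove_edge(a, u)
    out._remove_edge(b, v)
    out._add_edge(a, v)
    out._add_edge(b, u)
    return out


def perturb_to_ad(species_tree: UnrootedTree, target_ad: float, seed=None,
                  max_moves: Optional[int] = None) -> UnrootedTree:
    """Random NNI walk from the species tree until the normalized RF first
    reaches the target (or a move cap, whichever comes first).

    Individual gene trees overshoot the target by at most one NNI step
    (2 / (2(n-3)) in normalized RF), so the mean over many genes tracks the
    target closely.
    """
    if not 0.0 <= target_ad <= 1.0:
        raise ValueError("target_ad must be in [0, 1]")
    if target_ad == 0.0:
        return species_tree.copy()
    rng = _as_rng(seed)
    if max_moves is None:
        max_moves = 50 * species_tree.n_leaves
    current = species_tree
    for _ in range(max_moves):
        if normalized_rf(species_tree, current) >= target_ad:
            break
        current = nni_move(current, rng)
    return current


def clade_size_multiset(species_tree: UnrootedTree, outgroup: str) -> List[int]:
    """Sizes of the non-trivial clades of the species tree rooted at the
    outgroup (root clade and leaves excluded); sorted multiset."""
    view = root_at_leaf_and_prune(species_tree, outgroup)
    sizes = [
        len(view.clade(v))
        for v in view._clades
        if v != view.root and view.children(v)
    ]
    return sorted(sizes)


def deletion_protocol(species_tree: UnrootedTree,
                      gene_trees: Sequence[UnrootedTree],
                      config: SimulationConfig,
                      seed=None,
                      return_records: bool = False):
    """Delete taxa from a random subset of the genes.

    ``fraction_incomplete`` of the genes are selected uniformly at random;
    each selected gene loses n taxa (n drawn uniformly from the clade-size
    multiset of the rooted species tree, taxa drawn uniformly without
    replacement), redrawing until at least 3 leaves survive.  Unselected
    genes pass through untouched.
    """
    if config.outgroup not in species_tree.leaf_labels:
        raise LeafSetError(f"outgroup {config.outgroup!r} not in species tree",
                           only_in_b=[config.outgroup])
    rng = _as_rng(config.seed if seed is None else seed)
    multiset = clade_size_multiset(species_tree, config.outgroup)
    n_genes = len(gene_trees)
    n_incomplete = int(round(config.fraction_incomplete * n_genes))
    chosen = set(rng.choice(n_genes, size=n_incomplete, replace=False).tolist())
    out: List[UnrootedTree] = []
    records: List[Dict] = []
    for i, gene in enumerate(gene_trees):
        if i not in chosen:
            out.append(gene)
            records.append({"gene": i, "deleted": (), "n_deleted": 0})
            continue
        labels = sorted(gene.leaf_labels)
        if not any(len(labels) - k >= 3 for k in multiset):
            raise TreeValidationError(
                "no clade size in the multiset leaves >= 3 taxa in the gene tree"
            )
        while True:
            k = int(multiset[rng.integers(len(multiset))])
            if len(labels) - k >= 3:
                deleted = [labels[j] for j in rng.choice(len(labels), size=k,
                                                         replace=False)]
                break
        kept = set(labels) - set(deleted)
        out.append(restrict(gene, kept))
        records.append({"gene": i, "deleted": tuple(sorted(deleted)),
                        "n_deleted": k})
    if return_records:
        return out, records
    return out


# ---------------------------------------------------------------------------
# Greedy consensus
# ---------------------------------------------------------------------------

def _compatible(c1: FrozenSet[str], c2: FrozenSet[str]) -> bool:
    """Clusters avoiding a common reference leaf are compatible iff
    disjoint or nested."""
    inter = c1 & c2
    return not inter or inter == c1 or inter == c2


def tree_from_bipartitions(leaves, bips: Sequence[Bipartition]) -> UnrootedTree:
    """Build the (possibly multifurcating) tree realizing a pairwise
    compatible set of nontrivial splits of ``leaves``."""
    leaves = frozenset(leaves)
    rho = min(leaves)
    clusters = []
    for bip in bips:
        c = bip.side_b if rho in bip.side_a else bip.side_a
        clusters.append(c)
    clusters = sorted(set(clusters), key=lambda c: (-len(c), sorted(c)))
    tree = UnrootedTree()
    root = tree._new_node()
    node_for: Dict[FrozenSet[str], int] = {}
    parents: List[FrozenSet[str]] = []
    for c in clusters:
        parent = root
        for p in parents:
            if c < p:
                parent = node_for[p]  # clusters sorted by size: first superset wins
                break
        node = tree._new_node()
        tree._add_edge(parent, node)
        node_for[c] = node
        parents.insert(0, c)
    parents_sorted = sorted(node_for, key=len)
    for lab in sorted(leaves):
        if lab == rho:
            tree.attach_leaf(root, lab)
            continue
        parent = root
        for c in parents_sorted:
            if lab in c:
                parent = node_for[c]
                break
        tree.attach_leaf(parent, lab)
    tree.suppress_degree_two()
    return tree


def greedy_consensus(trees: Sequence[UnrootedTree]) -> UnrootedTree:
    """Greedy (extended majority-rule) consensus of trees on one leaf set.

    Nontrivial splits are ranked by frequency (ties broken by canonical
    split order) and accepted in descending order whenever compatible with
    everything accepted so far.  The result can be multifurcating.
    """
    if not trees:
        raise TreeValidationError("greedy consensus needs at least one tree")
    leaves = trees[0].leaf_labels
    for t in trees[1:]:
        if t.leaf_labels != leaves:
            raise LeafSetError(
                "greedy consensus requires identical leaf sets",
                only_in_a=leaves - t.leaf_labels,
                only_in_b=t.leaf_labels - leaves,
            )
    counts: Counter = Counter()
    for t in trees:
        counts.update(bipartitions(t))
    ranked = sorted(counts, key=lambda b: (-counts[b], b.sort_key()))
    rho = min(leaves)
    accepted: List[Bipartition] = []
    accepted_clusters: List[FrozenSet[str]] = []
    for bip in ranked:
        c = bip.side_b if rho in bip.side_a else bip.side_a
        if all(_compatible(c, other) for other in accepted_clusters):
            accepted.append(bip)
            accepted_clusters.append(c)
    return tree_from_bipartitions(leaves, accepted)


def resolve_polytomies(tree: UnrootedTree, seed=None) -> UnrootedTree:
    """Refine every multifurcation into random bifurcations (seeded).

    Each polytomy is resolved by repeatedly splitting off a random pair of
    neighbours onto a fresh node until all internal degrees are 3.
    """
    rng = _as_rng(seed)
    out = tree.copy()
    while True:
        poly = [u for u in out.nodes()
                if not out.is_leaf(u) and out.degree(u) > 3]
        if not poly:
            break
        u = min(poly)
        nbrs = sorted(out.neighbors(u))
        i, j = sorted(rng.choice(len(nbrs), size=2, replace=False).tolist())
        a, b = nbrs[i], nbrs[j]
        w = out._new_node()
        out._remove_edge(a, u)
        out._remove_edge(b, u)
        out._add_edge(a, w)
        out._add_edge(b, w)
        out._add_edge(u, w)
    return out


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """Species tree, complete gene trees, incomplete gene trees, records."""

    config: SimulationConfig
    species_tree: UnrootedTree
    gene_trees: List[UnrootedTree]
    incomplete_gene_trees: List[UnrootedTree]
    deletion_records: List[Dict]
    realized_ad: float


def simulate_dataset(config: SimulationConfig,
                     gene_sampler: Optional[Callable] = None) -> SimulatedDataset:
    """Generate one full synthetic dataset under ``config``.

    ``gene_sampler(species_tree, rng) -> UnrootedTree`` may replace the
    default NNI-walk discordance model.
    """
    rng = np.random.default_rng(config.seed)
    species = random_binary_tree(config.labels, rng)
    genes = []
    for _ in range(config.n_genes):
        if gene_sampler is not None:
            genes.append(gene_sampler(species, rng))
        else:
            genes.append(perturb_to_ad(species, config.target_ad, rng))
    realized = float(np.mean([normalized_rf(species, g) for g in genes]))
    incomplete, records = deletion_protocol(
        species, genes, config, seed=rng, return_records=True
    )
    return SimulatedDataset(
        config=config, species_tree=species, gene_trees=genes,
        incomplete_gene_trees=incomplete, deletion_records=records,
        realized_ad=realized,
    )
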