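"""Brute-force ground truth for the completion problem.

Enumerates every way of attaching the missing leaves, one edge at a time,
and reports the true minimum RF distance.  Used to certify the greedy
algorithm on small instances; the number of leaf-addition sequences for k
missing leaves over an ℓ-leaf gene tree is ∏_{i=0..k-1} (2(ℓ+i) - 3), so a
hard cap guards against accidental blow-ups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, List, Optional

from .completion import _check_instance, completion_lower_bound
from .errors import OracleCapError
from .tree import UnrootedTree, rf_distance

__all__ = ["CompletionEnumeration", "enumerate_completions", "brute_force_complete",
           "count_completion_sequences"]

DEFAULT_CAP = 10**6


def count_completion_sequences(n_gene_leaves: int, n_missing: int) -> int:
    total = 1
    for i in range(n_missing):
        total *= 2 * (n_gene_leaves + i) - 3
    return total


@dataclass
class CompletionEnumeration:
    """Result of exhaustively scanning all completions of one instance."""

    count: int
    best_rf: int
    best_tree: UnrootedTree
    lower_bound: int
    optima: Optional[List[UnrootedTree]] = None

    @property
    def matches_lower_bound(self) -> bool:
        return self.best_rf == self.lower_bound


def enumerate_completions(reference: UnrootedTree, gene: UnrootedTree,
                          cap: int = DEFAULT_CAP) -> Iterator[UnrootedTree]:
    """Yield every binary completion of the gene tree on the reference's taxa.

    Missing leaves are attached recursively to every edge; distinct
    attachment sequences can rebuild the same topology, and duplicates are
    yielded rather than filtered (the minimum is unaffected).
    """
    _check_instance(reference, gene)
    missing = sorted(reference.leaf_labels - gene.leaf_labels)
    predicted = count_completion_sequences(gene.n_leaves, len(missing))
    if predicted > cap:
        raise OracleCapError(
            f"{predicted} completion sequences exceed the cap of {cap}; "
            "refusing to enumerate"
        )

    def grow(tree: UnrootedTree, remaining: List[str]) -> Iterator[UnrootedTree]:
        if not remaining:
            yield tree
            return
        x, rest = remaining[0], remaining[1:]
        for u, v in tree.edges():
            bigger = tree.copy()
            bigger.add_leaf_on_edge(u, v, x)
            yield from grow(bigger, rest)

    yield from grow(gene, missing)


def brute_force_complete(reference: UnrootedTree, gene: UnrootedTree,
                         cap: int = DEFAULT_CAP,
                         collect_optima: bool = False) -> CompletionEnumeration:
    """Scan every completion and return the true optimum.

    Also records whether that optimum equals the closed-form lower bound
    r + 2m, which it must for every valid instance.
    """
    bound = completion_lower_bound(reference, gene)
    best_rf: Optional[int] = None
    best_tree: Optional[UnrootedTree] = None
    optima: List[UnrootedTree] = []
    count = 0
    for candidate in enumerate_completions(reference, gene, cap=cap):
        count += 1
        rf = rf_distance(reference, candidate)
        if best_rf is None or rf < best_rf:
            best_rf = rf
            best_tree = candidate
            if collect_optima:
                optima = [candidate]
        elif collect_optima and rf == best_rf and candidate not in optima:
            optima.append(candidate)
    return CompletionEnumeration(
        count=count, best_rf=best_rf, best_tree=best_tree,
        lower_bound=bound, optima=optima if collect_optima else None,
    )
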