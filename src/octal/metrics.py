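"""Quartet and matching distances between trees on the same leaf set.

Together with the RF distance these are the three evaluation metrics of the
package: all of them are zero exactly on topologically identical pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import FrozenSet, List, Optional

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import NotBinaryError, TreeValidationError
from .tree import UnrootedTree, bipartitions, _require_same_leaves

__all__ = ["DistanceResult", "quartet_distance", "matching_distance"]


@dataclass(frozen=True)
class DistanceResult:
    """A raw tree distance plus its normalization, where one is defined."""

    raw: float
    denominator: Optional[float] = None

    @property
    def normalized(self) -> Optional[float]:
        if self.denominator is None:
            return None
        return self.raw / self.denominator


def _bip_masks(tree: UnrootedTree, index: dict) -> List[int]:
    """Nontrivial splits as bitmasks over a fixed leaf ordering."""
    masks = []
    for bip in bipartitions(tree):
        m = 0
        for lab in bip.side_a:
            m |= 1 << index[lab]
        masks.append(m)
    return masks


def quartet_distance(t1: UnrootedTree, t2: UnrootedTree) -> DistanceResult:
    """Number of 4-leaf subsets inducing different topologies, out of C(n,4).

    Exact brute force: for each quartet {a,b,c,d} the induced topology is the
    pairing separated by some split of the tree (binary trees resolve every
    quartet).  Splits are held as bitmasks, so each check is a few integer
    operations.
    """
    leaves = sorted(_require_same_leaves(t1, t2))
    n = len(leaves)
    if n < 4:
        raise TreeValidationError("quartet distance needs at least 4 leaves")
    for name, t in (("first", t1), ("second", t2)):
        if not t.is_binary():
            raise NotBinaryError(f"{name} tree is not binary")
    index = {lab: i for i, lab in enumerate(leaves)}
    masks1 = _bip_masks(t1, index)
    masks2 = _bip_masks(t2, index)

    def topology(masks: List[int], qa: int, qb: int, qc: int, qd: int) -> int:
        # returns which leaf joins qa: 1 -> qb, 2 -> qc, 3 -> qd
        quartet = qa | qb | qc | qd
        for m in masks:
            inside = m & quartet
            if bin(inside).count("1") != 2:
                inside = ~m & quartet
                if bin(inside).count("1") != 2:
                    continue
            if not qa & inside:
                inside = quartet & ~inside
            if qb & inside:
                return 1
            if qc & inside:
                return 2
            return 3
        return 0  # unresolved (cannot happen for binary trees)

    bits = [1 << i for i in range(n)]
    differing = 0
    for a, b, c, d in combinations(range(n), 4):
        if topology(masks1, bits[a], bits[b], bits[c], bits[d]) != topology(
            masks2, bits[a], bits[b], bits[c], bits[d]
        ):
            differing += 1
    return DistanceResult(raw=differing, denominator=comb(n, 4))


def matching_distance(t1: UnrootedTree, t2: UnrootedTree) -> DistanceResult:
    """Minimum-weight perfect matching between the two nontrivial split sets.

    The weight of pairing split A|B with C|D is min(|A Δ C|, |A Δ D|) — the
    number of leaves that must move to turn one split into the other,
    independent of side orientation.  Solved exactly with the Hungarian
    algorithm.  No normalization is defined; only the raw value is reported.
    """
    leaves = sorted(_require_same_leaves(t1, t2))
    if len(leaves) < 4:
        raise TreeValidationError("matching distance needs at least 4 leaves")
    for name, t in (("first", t1), ("second", t2)):
        if not t.is_binary():
            raise NotBinaryError(f"{name} tree is not binary")
    index = {lab: i for i, lab in enumerate(leaves)}
    m1 = _bip_masks(t1, index)
    m2 = _bip_masks(t2, index)
    if len(m1) != len(m2):
        raise TreeValidationError(
            "matching distance needs equal bipartition counts "
            f"({len(m1)} vs {len(m2)})"
        )
    full = (1 << len(leaves)) - 1
    weights = np.empty((len(m1), len(m2)), dtype=np.int64)
    for i, a in enumerate(m1):
        for j, c in enumerate(m2):
            direct = bin(a ^ c).count("1")
            flipped = bin(a ^ (full & ~c)).count("1")
            weights[i, j] = direct if direct < flipped else flipped
    rows, cols = linear_sum_assignment(weights)
    return DistanceResult(raw=int(weights[rows, cols].sum()), denominator=None)
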