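"""Completion engine: edge classification, leaf addition, superleaves,
and the r + 2m optimality certificate."""

import numpy as np
import pytest

import octal as oc
from octal.completion import classify_edges
from octal.errors import LeafSetError, NotBinaryError, TreeValidationError
from octal.tree import Bipartition

from conftest import make_labels, random_instance


class TestClassifyEdges:
    def test_restriction_of_reference_is_all_shared(self, rng):
        reference = oc.random_binary_tree(make_labels(8), rng)
        gene = oc.restrict(reference, set(make_labels(6)))
        corr = classify_edges(reference, gene)
        assert not corr.unique_reference and not corr.unique_gene
        # one pair per split, trivial ones included: (n-3) + n edges
        assert len(corr.pairs) == (6 - 3) + 6

    def test_totally_conflicting_pair_shares_only_leaf_edges(self):
        # 5-leaf trees with disjoint nontrivial split sets
        reference = oc.parse_newick("((a,b),(c,(d,e)));")
        gene = oc.parse_newick("((a,c),(e,(b,d)));")
        assert oc.rf_distance(reference, gene) == 4  # no shared internal split
        corr = classify_edges(reference, gene)
        assert all(b.is_trivial for b in corr.pairs)
        assert len(corr.unique_gene) == 2

    def test_unique_count_is_half_the_rf_distance(self, rng):
        for _ in range(20):
            reference, gene = random_instance(rng, n_min=6, n_max=10)
            corr = classify_edges(reference, gene)
            r = oc.rf_distance(oc.restrict(reference, gene.leaf_labels), gene)
            assert len(corr.unique_gene) == len(corr.unique_reference) == r // 2
            assert corr.rf == r

    def test_hashed_and_direct_methods_agree(self, rng):
        for _ in range(10):
            reference, gene = random_instance(rng, n_min=6, n_max=10)
            fast = classify_edges(reference, gene, method="hashed")
            slow = classify_edges(reference, gene, method="direct")
            assert fast.shared == slow.shared
            assert fast.unique_gene == slow.unique_gene

    def test_alien_gene_taxa_rejected(self):
        with pytest.raises(LeafSetError):
            classify_edges(oc.parse_newick("((a,b),(c,d));"),
                           oc.parse_newick("((a,b),(c,zz));"))


class TestAddLeaf:
    def test_placing_into_own_restriction_recovers_reference_topology(self, rng):
        reference = oc.random_binary_tree(make_labels(8), rng)
        keep = set(make_labels(8)[:-1])
        gene = oc.restrict(reference, keep)
        missing = sorted(reference.leaf_labels - keep)[0]
        result = oc.add_leaf(gene, reference, missing)
        assert oc.rf_distance(reference, result) == 0

    def test_result_is_binary_and_restricts_back(self, rng):
        for _ in range(20):
            reference, gene = random_instance(rng, n_min=6, n_max=9)
            x = sorted(reference.leaf_labels - gene.leaf_labels)[0]
            result = oc.add_leaf(gene, reference, x)
            assert result.is_binary()
            assert oc.restrict(result, gene.leaf_labels) == gene

    def test_single_type_two_leaf_raises_rf_by_exactly_two(self, rng):
        found = 0
        while found < 10:
            reference, gene = _single_missing_instance(rng)
            (x,) = reference.leaf_labels - gene.leaf_labels
            (sl,) = oc.superleaf_decomposition(reference, gene)
            if not sl.is_type_two:
                continue
            found += 1
            before = oc.rf_distance(oc.restrict(reference, gene.leaf_labels), gene)
            completed = oc.add_leaf(gene, reference, x)
            assert oc.rf_distance(reference, completed) == before + 2

    def test_shared_edges_survive_each_insertion(self, rng):
        """After AddLeaf subdivides e', every other shared edge stays shared."""
        for _ in range(15):
            reference, gene = random_instance(rng, n_min=6, n_max=10)
            report = oc.octal(reference, gene, track_shared=True)
            for rec in report.insertions:
                x = rec.taxon
                for bip in rec.shared_before:
                    if bip == rec.subdivided_split:
                        continue
                    variants = {
                        Bipartition(bip.side_a | {x}, bip.side_b),
                        Bipartition(bip.side_a, bip.side_b | {x}),
                    }
                    assert variants & rec.shared_after, (
                        f"shared split {bip} lost when adding {x}"
                    )

    def test_duplicate_and_alien_taxa_rejected(self):
        reference = oc.parse_newick("((a,b),(c,(d,e)));")
        gene = oc.restrict(reference, {"a", "b", "c", "d"})
        with pytest.raises(TreeValidationError):
            oc.add_leaf(gene, reference, "a")
        with pytest.raises(LeafSetError):
            oc.add_leaf(gene, reference, "zz")


def _single_missing_instance(rng, n_min=6, n_max=9):
    n = int(rng.integers(n_min, n_max + 1))
    labels = make_labels(n)
    reference = oc.random_binary_tree(labels, rng)
    x = str(rng.choice(labels))
    keep = sorted(set(labels) - {x})
    gene = oc.random_binary_tree(keep, rng)
    return reference, gene


class TestSuperleafDecomposition:
    def test_no_missing_taxa_means_no_superleaves(self, rng):
        t = oc.random_binary_tree(make_labels(6), rng)
        gene = oc.random_binary_tree(make_labels(6), rng)
        assert oc.superleaf_decomposition(t, gene) == []

    def test_pendant_cherry_is_single_type_one_superleaf(self):
        reference = oc.parse_newick("((a,b),((r,s),(c,d)));")
        gene = oc.restrict(reference, {"a", "b", "c", "d"})
        (sl,) = oc.superleaf_decomposition(reference, gene)
        assert sl.members == {"r", "s"}
        assert sl.type == 1
        assert sl.attachment_split == Bipartition({"a", "b"}, {"c", "d"})

    def test_members_partition_the_missing_taxa(self, rng):
        for _ in range(20):
            reference, gene = random_instance(rng, n_min=7, n_max=12, max_missing=4)
            sls = oc.superleaf_decomposition(reference, gene)
            members = [m for sl in sls for m in sl.members]
            assert sorted(members) == sorted(reference.leaf_labels - gene.leaf_labels)

    def test_type_matches_attachment_split_presence(self, rng):
        for _ in range(20):
            reference, gene = random_instance(rng, n_min=7, n_max=10, max_missing=3)
            gene_splits = oc.bipartitions(gene, include_trivial=True)
            for sl in oc.superleaf_decomposition(reference, gene):
                shared = sl.attachment_split.is_trivial or sl.attachment_split in gene_splits
                assert (sl.type == 1) == shared


class TestLowerBound:
    def test_zero_for_compatible_instance(self, rng):
        reference = oc.random_binary_tree(make_labels(8), rng)
        gene = oc.restrict(reference, set(make_labels(5)))
        assert oc.completion_lower_bound(reference, gene) == 0

    def test_conflict_plus_one_type_two_superleaf_gives_four(self):
        # 7-leaf instance: r = 2 (one conflicting split) and the missing
        # leaf q hangs off a unique edge of the reference -> m = 1.
        reference = oc.parse_newick("((a,b),(((c,d),q),(e,f)));")
        gene = oc.parse_newick("((a,b),(c,(d,(e,f))));")
        r = oc.rf_distance(oc.restrict(reference, gene.leaf_labels), gene)
        sls = oc.superleaf_decomposition(reference, gene)
        assert r == 2 and len(sls) == 1 and sls[0].is_type_two
        assert oc.completion_lower_bound(reference, gene) == 4
        assert oc.octal(reference, gene).achieved_rf == 4
        assert oc.brute_force_complete(reference, gene).best_rf == 4


class TestOctal:
    def test_compatible_instance_completes_to_reference(self, rng):
        reference = oc.random_binary_tree(make_labels(9), rng)
        gene = oc.restrict(reference, set(make_labels(6)))
        report = oc.octal(reference, gene)
        assert report.r == report.m == report.achieved_rf == 0
        assert oc.rf_distance(report.tree, reference) == 0

    def test_certificate_and_restriction_identity(self, rng):
        for _ in range(30):
            reference, gene = random_instance(rng, n_min=6, n_max=14, max_missing=5)
            report = oc.octal(reference, gene)
            assert report.achieved_rf == report.lower_bound == report.r + 2 * report.m
            assert report.is_certified
            assert oc.restrict(report.tree, gene.leaf_labels) == gene
            assert report.tree.is_binary()

    def test_superleaf_topology_preserved(self, rng):
        for _ in range(20):
            reference, gene = random_instance(rng, n_min=7, n_max=12, max_missing=4)
            report = oc.octal(reference, gene)
            for sl in oc.superleaf_decomposition(reference, gene):
                if len(sl.members) < 2:
                    continue
                assert oc.restrict(report.tree, sl.members) == oc.restrict(
                    reference, sl.members
                )

    def test_per_superleaf_increment_law(self, rng):
        """First insertion of a Type II superleaf costs RF +2; everything
        else (Type I firsts and later members) costs 0."""
        checked = 0
        while checked < 10:
            reference, gene = random_instance(rng, n_min=7, n_max=12, max_missing=4)
            sls = oc.superleaf_decomposition(reference, gene)
            member_of = {m: sl for sl in sls for m in sl.members}
            current = gene
            prev_rf = oc.rf_distance(oc.restrict(reference, current.leaf_labels), current)
            seen = set()
            for x in sorted(reference.leaf_labels - gene.leaf_labels):
                current = oc.add_leaf(current, reference, x)
                now = oc.rf_distance(oc.restrict(reference, current.leaf_labels), current)
                sl = member_of[x]
                first = id(sl) not in seen
                seen.add(id(sl))
                expected = 2 if (first and sl.is_type_two) else 0
                assert now - prev_rf == expected, (x, sl.type, first)
                prev_rf = now
            checked += 1

    def test_insertion_order_does_not_change_the_optimum(self, rng):
        for _ in range(10):
            reference, gene = random_instance(rng, n_min=7, n_max=11, max_missing=4)
            values = {
                oc.octal(reference, gene, order="random", seed=s).achieved_rf
                for s in range(8)
            }
            values.add(oc.octal(reference, gene).achieved_rf)
            assert len(values) == 1

    def test_preconditions_enforced(self):
        reference = oc.parse_newick("((a,b),(c,(d,e)));")
        with pytest.raises(TreeValidationError):
            oc.octal(reference, oc.parse_newick("(a,b);"))
        with pytest.raises(NotBinaryError):
            oc.octal(reference, oc.parse_newick("(a,b,c,d);"))
        with pytest.raises(LeafSetError):
            oc.octal(reference, oc.parse_newick("((a,b),(c,zz));"))
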