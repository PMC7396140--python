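import math

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from microko import phylogeny as ph
from microko import synthetic_data as sd
from microko.io_formats import QualityRead

from conftest import patristic_matrix, rf_distance


def read_with_quals(quals, bases=None):
    quals = tuple(quals)
    bases = bases or "A" * len(quals)
    return QualityRead("r", bases, quals)


class TestTrimReads:
    def test_leading_strips_low_quality_prefix(self):
        read = read_with_quals([10, 16] + [40] * 248)
        (out,) = ph.trim_reads([read])
        assert len(out) == 248
        assert out.quals[0] == 40
        assert out.bases == read.bases[2:]

    def test_average_quality_drop(self):
        read = read_with_quals([24] * 250)
        assert ph.trim_reads([read]) == []

    def test_min_length_drop(self):
        read = read_with_quals([40] * 199)
        assert ph.trim_reads([read]) == []

    def test_trailing_strips_low_quality_suffix(self):
        read = read_with_quals([40] * 230 + [5] * 20)
        (out,) = ph.trim_reads([read])
        assert len(out) == 230

    def test_fully_low_quality_read_dropped(self):
        read = read_with_quals([5] * 250)
        assert ph.trim_reads([read]) == []

    @given(
        quals=st.lists(st.integers(0, 42), min_size=1, max_size=60),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_never_increases_length_and_interior_quality_ok(self, quals):
        read = read_with_quals(quals)
        out = ph.trim_reads([read], min_len=0, avg_qual=0)
        if out:
            assert len(out[0]) <= len(read)
            assert out[0].quals[0] >= 17 and out[0].quals[-1] >= 17
            # trimmed read is a contiguous slice of the original
            assert out[0].bases in read.bases


class TestDereplicate:
    def test_counts_and_order(self):
        assert ph.dereplicate(["ACGT", "ACGT", "ACGA"]) == [("ACGT", 2), ("ACGA", 1)]

    def test_all_distinct_sorted_lexicographically(self):
        out = ph.dereplicate(["T", "A", "G"])
        assert out == [("A", 1), ("G", 1), ("T", 1)]

    def test_total_count_conserved(self):
        seqs = ["A"] * 3 + ["C"] * 5 + ["G"]
        assert sum(c for _, c in ph.dereplicate(seqs)) == len(seqs)

    def test_head_is_most_abundant_unique(self):
        seqs = ["AA"] * 2 + ["CC"] * 5 + ["GG"]
        assert ph.dereplicate(seqs)[0] == ("CC", 5)


class TestK2PDistance:
    def test_identical_sequences_give_exact_zero(self):
        d = ph.k2p_distance("ACGTACGT", "ACGTACGT")
        assert d == 0.0 and math.copysign(1, d) == 1.0

    def test_pure_transition_closed_form(self):
        # 10 transitions in 100 sites: d = -1/2 ln(0.8)
        d = ph.k2p_distance("A" * 90 + "G" * 10, "A" * 100)
        assert d == pytest.approx(0.1115717756571048, abs=1e-12)

    def test_mixed_closed_form(self):
        # P = Q = 0.25: d = -1/2 ln(0.25) - 1/4 ln(0.5)
        a = "A" * 100
        b = "A" * 50 + "G" * 25 + "C" * 25
        assert ph.k2p_distance(a, b) == pytest.approx(0.8664339757, abs=1e-9)

    def test_symmetric(self):
        a, b = "ACGTTGCA", "AGGTTGTA"
        assert ph.k2p_distance(a, b) == ph.k2p_distance(b, a)

    def test_pairwise_deletion_ignores_gaps_and_ambiguity(self):
        assert ph.k2p_distance("AC-TN", "ACGTA") == 0.0

    def test_saturation_returns_infinity(self):
        # all transversions: Q = 1 is outside the model's domain
        assert ph.k2p_distance("AAAA", "CCCC") == math.inf

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="lengths differ"):
            ph.k2p_distance("ACG", "AC")

    def test_no_comparable_sites_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            ph.k2p_distance("--", "AC")


class TestK2PMatrix:
    def test_identical_sequences_give_zero_matrix(self):
        aln = {"a": "ACGT", "b": "ACGT", "c": "ACGT"}
        dm = ph.k2p_matrix(aln)
        assert (dm.values == 0).all()

    def test_exactly_symmetric(self):
        tree = sd.random_tree(5, seed=3)
        aln = sd.simulate_sequences(sd.SeqSimConfig(seed=4, tree=tree, length=500))
        dm = ph.k2p_matrix(aln)
        assert (dm.values == dm.values.T).all()

    def test_saturated_pair_warns(self):
        aln = {"a": "AAAA", "b": "CCCC", "c": "AAAA"}
        with pytest.warns(ph.SaturationWarning):
            dm = ph.k2p_matrix(aln)
        assert dm.has_saturation

    def test_estimates_converge_to_path_lengths(self):
        tree = sd.random_tree(4, seed=8, bl_range=(0.05, 0.2))
        aln = sd.simulate_sequences(
            sd.SeqSimConfig(seed=9, tree=tree, length=50_000, kappa=2.0)
        )
        dm = ph.k2p_matrix(aln)
        truth = patristic_matrix(tree)
        est = np.array(
            [[dm[(i, j)] for j in truth.labels] for i in truth.labels]
        )
        assert np.abs(est - truth.values).max() < 0.01

    def test_too_few_sequences_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            ph.k2p_matrix({"a": "ACGT", "b": "ACGT"})


class TestNJTree:
    def test_three_taxon_worked_example(self):
        dm = ph.DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
        )
        tree = ph.nj_tree(dm)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths == {"A": 0.5, "B": 1.5, "C": 2.5}

    def test_additive_matrix_reproduced_exactly(self):
        tree = sd.random_tree(4, seed=21)
        dm = patristic_matrix(tree)
        nj = ph.nj_tree(dm)
        pdm = nj.phylogenetic_distance_matrix()
        tns = nj.taxon_namespace
        for i, a in enumerate(dm.labels):
            for b in dm.labels[i + 1 :]:
                d = pdm.patristic_distance(tns.get_taxon(a), tns.get_taxon(b))
                assert d == pytest.approx(dm[(a, b)], abs=1e-9)

    def test_label_permutation_gives_isomorphic_tree(self):
        tree = sd.random_tree(7, seed=33)
        dm = patristic_matrix(tree)
        perm = [3, 0, 6, 2, 5, 1, 4]
        dm2 = ph.DistanceMatrix(
            [dm.labels[i] for i in perm], dm.values[np.ix_(perm, perm)]
        )
        assert rf_distance(ph.nj_tree(dm), ph.nj_tree(dm2)) == 0

    def test_matches_independent_nj_implementation(self):
        # cross-check against scikit-bio's neighbor joining on the same
        # additive matrix
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        tree = sd.random_tree(8, seed=55)
        dm = patristic_matrix(tree)
        ours = ph.nj_tree(dm)
        sk = skbio_nj(skbio.DistanceMatrix(dm.values, ids=dm.labels))
        sk_tree = dendropy.Tree.get(data=str(sk), schema="newick")
        assert rf_distance(ours, sk_tree) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_topology_recovery_on_exact_matrices(self, seed):
        n = 6 + seed % 5
        tree = sd.random_tree(n, seed=100 + seed)
        assert rf_distance(ph.nj_tree(patristic_matrix(tree)), tree) == 0

    def test_statistical_recovery_from_simulated_alignments(self):
        hits = 0
        for seed in range(10):
            tree = sd.random_tree(8, seed=200 + seed, bl_range=(0.05, 0.3))
            aln = sd.simulate_sequences(
                sd.SeqSimConfig(seed=300 + seed, tree=tree, length=5000, kappa=2.0)
            )
            if rf_distance(ph.nj_tree(ph.k2p_matrix(aln)), tree) == 0:
                hits += 1
        assert hits >= 9

    def test_infinite_distance_rejected(self):
        vals = np.array([[0, 1, np.inf], [1, 0, 1], [np.inf, 1, 0]])
        with pytest.raises(ValueError, match="infinite"):
            ph.nj_tree(ph.DistanceMatrix(["a", "b", "c"], vals))

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            ph.nj_tree(ph.DistanceMatrix(["a", "b"], np.array([[0.0, 1], [1, 0]])))


class TestRootWithOutgroup:
    def _quartet(self):
        tree = dendropy.Tree.get(
            data="((A:0.1,B:0.2):0.15,(C:0.3,O:0.25):0.25);",
            schema="newick",
        )
        tree.is_rooted = False
        return tree

    def test_single_outgroup_partitions_leaves(self):
        rooted = ph.root_with_outgroup(self._quartet(), {"O"})
        children = rooted.seed_node.child_nodes()
        assert len(children) == 2
        sides = [
            {lf.taxon.label for lf in ch.leaf_iter()} for ch in children
        ]
        assert {"O"} in sides
        assert {"A", "B", "C"} in sides

    def test_root_edge_split_at_midpoint(self):
        rooted = ph.root_with_outgroup(self._quartet(), {"O"})
        lengths = sorted(ch.edge.length for ch in rooted.seed_node.child_nodes())
        assert lengths[0] == pytest.approx(0.125)
        assert lengths[1] == pytest.approx(0.125)

    def test_monophyletic_pair_outgroup(self):
        tree = dendropy.Tree.get(
            data="((A:0.1,B:0.2):0.15,(O1:0.3,O2:0.25):0.4,C:0.2);",
            schema="newick",
        )
        tree.is_rooted = False
        rooted = ph.root_with_outgroup(tree, {"O1", "O2"})
        sides = [
            {lf.taxon.label for lf in ch.leaf_iter()}
            for ch in rooted.seed_node.child_nodes()
        ]
        assert {"O1", "O2"} in sides

    def test_non_monophyletic_outgroup_rejected(self):
        with pytest.raises(ValueError, match="monophyletic"):
            ph.root_with_outgroup(self._quartet(), {"A", "O"})

    def test_outgroup_of_all_leaves_rejected(self):
        with pytest.raises(ValueError, match="every leaf"):
            ph.root_with_outgroup(self._quartet(), {"A", "B", "C", "O"})

    def test_missing_outgroup_taxon_rejected(self):
        with pytest.raises(ValueError, match="not in tree"):
            ph.root_with_outgroup(self._quartet(), {"Z"})

    def test_rooting_preserves_unrooted_topology(self):
        tree = sd.random_tree(7, seed=77)
        rooted = ph.root_with_outgroup(tree, {"t1"})
        assert rf_distance(rooted, tree) == 0

    def test_input_tree_not_mutated(self):
        tree = self._quartet()
        before = tree.as_string(schema="newick")
        ph.root_with_outgroup(tree, {"O"})
        assert tree.as_string(schema="newick") == before
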