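import warnings

import numpy as np
import pytest

from oracles import (
    best_topology_least_squares,
    newick_splits,
    random_additive_tree,
    topology_splits,
)

from afgpkit.family_evolution import (
    DistanceMatrix,
    FamilyTree,
    assign_orthologs,
    bootstrap_support,
    expansion_order,
    nj_tree,
    nj_tree_from_seqs,
    pairwise_distance,
    robinson_foulds,
)
from afgpkit.synthetic_data import SimConfig, simulate_species_pair


class TestPairwiseDistance:
    def test_identical_sequences_zero(self):
        m = pairwise_distance([("a", "ACGTACGT"), ("b", "ACGTACGT")])
        assert m.get("a", "b") == 0.0

    def test_p_distance_by_definition(self):
        a = "A" * 90 + "C" * 10
        b = "A" * 90 + "G" * 10
        m = pairwise_distance([("a", a), ("b", b)], model="p")
        assert m.get("a", "b") == pytest.approx(0.10)

    def test_jc69_closed_form_at_ten_percent(self):
        a = "A" * 90 + "C" * 10
        b = "A" * 90 + "G" * 10
        m = pairwise_distance([("a", a), ("b", b)], model="JC69")
        assert m.get("a", "b") == pytest.approx(0.1073, abs=1e-4)

    def test_pairwise_deletion_of_gap_and_n_columns(self):
        a = "ACGT-CGTNA"
        b = "ACGTACGTAA"
        # valid columns: all but the '-' and 'N' ones (8 sites, 0 mismatches)
        m = pairwise_distance([("a", a), ("b", b)], model="p")
        assert m.get("a", "b") == 0.0

    def test_saturated_jc_capped_with_warning(self):
        a = "A" * 100
        b = "C" * 80 + "A" * 20
        with pytest.warns(UserWarning, match="saturated"):
            m = pairwise_distance([("a", a), ("b", b)], model="JC69",
                                  saturation_cap=5.0)
        assert m.get("a", "b") == 5.0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            pairwise_distance([("a", "ACGT"), ("b", "ACG")])


class TestNeighborJoining:
    def test_three_leaves_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = nj_tree(DistanceMatrix(["A", "B", "C"], d))
        # terminal branches: (dAB+dAC-dBC)/2 = 1, (dAB+dBC-dAC)/2 = 2,
        # (dAC+dBC-dAB)/2 = 3
        assert tree.newick == "(A:1,B:2,C:3);"

    def test_two_leaves_degenerate(self):
        d = np.array([[0, 4], [4, 0]], float)
        tree = nj_tree(DistanceMatrix(["A", "B"], d))
        assert tree.newick == "(A:2,B:2);"

    def test_four_leaf_additive_topology(self):
        # tree ((A,B),(C,D)) with internal edge 2
        d = np.array(
            [[0, 2, 5, 5],
             [2, 0, 5, 5],
             [5, 5, 0, 2],
             [5, 5, 2, 0]], float,
        )
        tree = nj_tree(DistanceMatrix(list("ABCD"), d))
        splits = newick_splits(tree.newick, list("ABCD"))
        assert splits == {frozenset("AB")}

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_recovers_random_additive_matrices(self, n, rng):
        for _ in range(5):
            labels, edges, d = random_additive_tree(rng, n)
            tree = nj_tree(DistanceMatrix(labels, d))
            assert newick_splits(tree.newick, labels) == topology_splits(
                edges, labels
            )

    @pytest.mark.parametrize("n", [5, 6])
    def test_agrees_with_exhaustive_least_squares(self, n, rng):
        for _ in range(3):
            labels, _, d = random_additive_tree(rng, n)
            tree = nj_tree(DistanceMatrix(labels, d))
            best_edges, resid = best_topology_least_squares(labels, d)
            assert resid < 1e-18
            assert newick_splits(tree.newick, labels) == topology_splits(
                best_edges, labels
            )

    def test_matches_scikit_bio_on_random_matrices(self, rng):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sknj

        for _ in range(5):
            n = int(rng.integers(4, 9))
            pts = rng.random((n, 5))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            labels = [f"L{i}" for i in range(n)]
            mine = nj_tree(DistanceMatrix(labels, d))
            theirs = FamilyTree(str(sknj(SkDM(d, ids=labels))))
            assert robinson_foulds(mine, theirs) == 0

    def test_input_order_invariance(self, rng):
        labels, _, d = random_additive_tree(rng, 6)
        perm = rng.permutation(6)
        t1 = nj_tree(DistanceMatrix(labels, d))
        t2 = nj_tree(
            DistanceMatrix([labels[i] for i in perm], d[np.ix_(perm, perm)])
        )
        assert robinson_foulds(t1, t2) == 0

    def test_bootstrap_support_is_high_on_clean_signal(self):
        seqs = [
            ("A", "A" * 100 + "C" * 40),
            ("B", "A" * 100 + "C" * 38 + "GG"),
            ("C", "T" * 30 + "A" * 70 + "C" * 40),
            ("D", "T" * 30 + "A" * 70 + "C" * 36 + "GGGG"),
        ]
        tree, support = bootstrap_support(seqs, n_replicates=50, seed=3)
        assert support and min(support.values()) > 0.6


class TestOrthologAssignment:
    T5 = FamilyTree("((A_g1:1,B_g1:1):1,(A_g2:1,B_g2:1):1,A_g3:2);")
    T3 = FamilyTree("((A_g1:1,B_g1:1):1,(A_g2:1,B_g2:1):1,A_g3:2);")
    CTERM = {"A_g1": "PVG", "B_g1": "PVG", "A_g2": "PVG", "B_g2": "PVG",
             "A_g3": "PVG"}

    def test_sisters_in_both_trees(self):
        pairs = assign_orthologs(self.T5, self.T3, self.CTERM)
        assert pairs == [("A_g1", "B_g1"), ("A_g2", "B_g2")]

    def test_cterm_mismatch_blocks_pair(self):
        cterm = dict(self.CTERM, B_g2="PVA")
        pairs = assign_orthologs(self.T5, self.T3, cterm)
        assert pairs == [("A_g1", "B_g1")]

    def test_missing_leaf_in_3prime_tree_accepted_from_5prime(self):
        t3 = FamilyTree("((A_g1:1,B_g1:1):1,A_g2:1,A_g3:2);")
        pairs = assign_orthologs(self.T5, t3, self.CTERM)
        assert ("A_g2", "B_g2") in pairs

    def test_cross_cherry_contradiction_rejected(self):
        t3 = FamilyTree("((A_g1:1,B_g2:1):1,(A_g2:1,B_g1:1):1,A_g3:2);")
        pairs = assign_orthologs(self.T5, t3, self.CTERM)
        assert ("A_g1", "B_g1") not in pairs

    def test_species_order_symmetry(self):
        pairs = assign_orthologs(self.T3, self.T5, self.CTERM)
        assert pairs == [("A_g1", "B_g1"), ("A_g2", "B_g2")]

    def test_perfect_recovery_on_well_separated_families(self):
        for seed in (2, 11):
            cfg = SimConfig(seed=seed, substitution_rate=0.0)
            fams, true_pairs, cterm = simulate_species_pair(
                cfg, divergence_generations=20
            )
            recs = fams["A"] + fams["B"]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t5 = nj_tree_from_seqs([(r.id, r.flank5) for r in recs])
                t3 = nj_tree_from_seqs([(r.id, r.flank3) for r in recs])
            pred = assign_orthologs(t5, t3, cterm)
            assert set(pred) == set(true_pairs)

    def test_recall_degrades_with_divergence(self):
        """Ortholog recall should fall (weakly) as flank divergence rises."""
        for seed in (2, 4, 7, 11):
            cfg = SimConfig(seed=seed, substitution_rate=0.0)
            recalls = []
            for div in (20, 200, 1500):
                fams, true_pairs, cterm = simulate_species_pair(
                    cfg, divergence_generations=div
                )
                recs = fams["A"] + fams["B"]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    t5 = nj_tree_from_seqs([(r.id, r.flank5) for r in recs])
                    t3 = nj_tree_from_seqs([(r.id, r.flank3) for r in recs])
                pred = set(assign_orthologs(t5, t3, cterm))
                recalls.append(len(pred & set(true_pairs)) / len(true_pairs))
            assert recalls[0] >= recalls[-1]
            assert all(a >= b - 1e-9 for a, b in zip(recalls, recalls[1:]))


class TestExpansionOrder:
    def test_long_branch_pseudogene_flagged_basal(self):
        tree = FamilyTree("((g1:0.3,g2:0.1):0.05,(g3:0.1,g4:0.1):0.05,g5:0.1);")
        order = expansion_order(
            tree,
            pseudogene_flags={"g1": True},
            clusters={g: "I" for g in ("g1", "g2", "g3", "g4", "g5")},
            shared_flank={},
        )
        assert order.basal == ["g1"]

    def test_dominant_shared_flank_is_duplicon_edge(self):
        tree = FamilyTree("((g1:0.1,g2:0.1):0.05,(g3:0.1,g4:0.1):0.05,g5:0.1);")
        shared = {
            frozenset(("g1", "g3")): 1300.0,
            frozenset(("g1", "g4")): 200.0,
            frozenset(("g2", "g3")): 150.0,
        }
        clusters = {"g1": "I", "g2": "I", "g5": "I", "g3": "II", "g4": "II"}
        order = expansion_order(tree, {}, clusters, shared)
        assert len(order.edges) == 1
        e = order.edges[0]
        assert {e["from"], e["to"]} == {"g1", "g3"}
        assert e["shared_flank_bp"] == 1300.0

    def test_star_tree_uniform_flanks_empty_order(self):
        tree = FamilyTree("(g1:0.1,g2:0.1,g3:0.1,g4:0.1);")
        shared = {
            frozenset(("g1", "g3")): 100.0,
            frozenset(("g1", "g4")): 100.0,
            frozenset(("g2", "g3")): 100.0,
            frozenset(("g2", "g4")): 100.0,
        }
        clusters = {"g1": "I", "g2": "I", "g3": "II", "g4": "II"}
        order = expansion_order(tree, {"g2": True}, clusters, shared)
        assert order.is_empty
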