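"""Sankoff scoring vs brute-force oracle, searches, bootstrap, consensus."""

import numpy as np
import pytest

from genechar import (
    CharacterMatrix,
    SearchConfig,
    TaxonSet,
    bootstrap,
    brute_force_length,
    build_character,
    build_matrix,
    character_length,
    consensus,
    exhaustive_search,
    heuristic_search,
    parse_newick,
    tree_length,
)
from genechar.parsimony import MatrixScorer, species_tree_from_genetree
from genechar.simulate import SimulationConfig, simulate_gene_trees, simulate_species_tree
from genechar.topology import UnrootedTree, enumerate_topologies, random_topology

from conftest import random_gene_tree


def topo(taxa, *splits):
    return UnrootedTree.from_splits(taxa, [frozenset(s) for s in splits])


@pytest.fixture
def abcd():
    return ("A", "B", "C", "D")


class TestCharacterLength:
    def test_worked_example_matching_topology(self, worked_character, abcd):
        t = topo(abcd, {"C", "D"})
        assert character_length(t, worked_character) == pytest.approx(16.66)

    def test_worked_example_conflicting_topologies(self, worked_character, abcd):
        for split in ({"B", "D"}, {"B", "C"}):
            t = topo(abcd, split)
            assert character_length(t, worked_character) == pytest.approx(21.66)

    def test_degenerate_character_scores_zero(self, abcd):
        ch = build_character(parse_newick("((A:0,B:0):0,(C:0,D:0):0);"))
        for t in enumerate_topologies(abcd):
            assert character_length(t, ch) == 0.0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            n = int(rng.integers(4, 7))
            gene = random_gene_tree(rng, n)
            ch = build_character(gene)
            taxa = tuple(sorted(gene.tip_labels()))
            t = random_topology(taxa, rng)
            assert character_length(t, ch) == pytest.approx(
                brute_force_length(t, ch), abs=1e-9
            )

    def test_missing_taxon_is_neutral(self, abcd):
        # character observed on A, B, C only; D enters as missing data
        gene = parse_newick("((A:1,B:2):1,C:3);", "g1")
        ch = build_character(gene, taxa=TaxonSet(abcd))
        assert ch.missing == frozenset({"D"})
        for t in enumerate_topologies(abcd):
            assert character_length(t, ch) == pytest.approx(
                brute_force_length(t, ch), abs=1e-9
            )

    def test_score_independent_of_internal_node_ids(self, worked_character, abcd):
        # same bipartition reached via different constructions
        a = topo(abcd, {"C", "D"})
        b = next(
            t for t in enumerate_topologies(abcd)
            if t.taxon_splits() == frozenset({frozenset({"C", "D"})})
        )
        assert character_length(a, worked_character) == pytest.approx(
            character_length(b, worked_character)
        )

    def test_unbalanced_pendants_collapse_character_to_star_bound(self):
        """Every topology can assign one shared ancestral haplotype to all
        internal nodes, so no topology ever scores above the star bound
        min_X sum_leaf cost(leaf, X).  When pendant branches dwarf the
        internal branch, the gene's own topology cannot beat that bound
        either: all topologies tie exactly and single-gene identifiability
        is lost (though no wrong tree is ever strictly preferred)."""
        gene = parse_newick("((A:0.1,B:0.1):0.1,(C:1.0,D:1.0):0.1);", "lba")
        ch = build_character(gene)
        star_bound = float(ch.cost.sum(axis=0).min())
        scores = [
            character_length(t, ch)
            for t in enumerate_topologies(("A", "B", "C", "D"))
        ]
        assert all(s == pytest.approx(star_bound, abs=1e-9) for s in scores)

    def test_brute_force_refuses_large_trees(self, worked_character):
        big = random_topology([f"T{i}" for i in range(8)], np.random.default_rng(0))
        with pytest.raises(ValueError, match="7 taxa"):
            brute_force_length(big, worked_character)


class TestTreeLength:
    def test_three_identical_characters(self, worked_tree, abcd):
        m = build_matrix([worked_tree.clone() for _ in range(3)], TaxonSet(abcd))
        t = topo(abcd, {"C", "D"})
        assert tree_length(t, m) == pytest.approx(3 * 16.66)

    def test_empty_matrix(self, abcd):
        m = CharacterMatrix(TaxonSet(abcd), [])
        assert tree_length(topo(abcd, {"C", "D"}), m) == 0.0

    def test_additivity(self, small_simulation):
        sp, trees, labels, taxa = small_simulation
        m = build_matrix(trees[:15], taxa)
        t = random_topology(taxa.names, np.random.default_rng(2))
        per = MatrixScorer(m).per_character(t)
        assert tree_length(t, m) == pytest.approx(per.sum())

    def test_weight_linearity(self, small_simulation):
        sp, trees, labels, taxa = small_simulation
        m1 = build_matrix(trees[:10], taxa)
        w = np.ones(10)
        w[3] = 2.0
        m2 = CharacterMatrix(taxa, m1.characters, weights=w)
        t = random_topology(taxa.names, np.random.default_rng(4))
        per = MatrixScorer(m1).per_character(t)
        assert tree_length(t, m2) - tree_length(t, m1) == pytest.approx(per[3])

    def test_mismatched_taxa_rejected(self, worked_tree, abcd):
        m = build_matrix([worked_tree], TaxonSet(abcd))
        other = topo(("A", "B", "C", "E"), {"C", "E"})
        with pytest.raises(ValueError, match="taxa"):
            tree_length(other, m)


class TestExhaustiveSearch:
    def test_single_clean_gene_recovers_own_topology(self, worked_tree, abcd):
        m = build_matrix([worked_tree], TaxonSet(abcd))
        res = exhaustive_search(m)
        assert res.evaluated == 3
        assert len(res.best_trees) == 1
        assert res.best_trees[0].taxon_splits() == frozenset({frozenset({"C", "D"})})
        assert res.score == pytest.approx(16.66)

    def test_mirror_conflict_ties(self, abcd):
        g1 = parse_newick("((A:1,B:1):1,(C:1,D:1):1);", "g1")
        g2 = parse_newick("((A:1,C:1):1,(B:1,D:1):1);", "g2")
        res = exhaustive_search(build_matrix([g1, g2], TaxonSet(abcd)))
        assert len(res.best_trees) == 2
        tied = {t.taxon_splits() for t in res.best_trees}
        assert frozenset({frozenset({"C", "D"})}) in tied
        assert frozenset({frozenset({"B", "D"})}) in tied

    def test_seven_taxon_count(self, small_simulation):
        sp, trees, labels, taxa = small_simulation
        res = exhaustive_search(build_matrix(trees[:20], taxa))
        assert res.evaluated == 945

    def test_too_many_taxa_redirects(self):
        taxa = TaxonSet(tuple(f"T{i}" for i in range(10)))
        with pytest.raises(ValueError, match="heuristic"):
            exhaustive_search(CharacterMatrix(taxa, []))

    def test_unique_recovery_on_clocklike_species_tree(self):
        """With internal branches comparable to pendant branches (here all
        equal), the characters resolve every split and the true topology is
        the unique optimum.  Ties appear only when pendants dwarf the
        internal branches (star-bound collapse) or an internal branch falls
        below the rounding resolution."""
        newick = (
            "((A:0.1,B:0.1):0.1,((C:0.1,D:0.1):0.1,"
            "(E:0.1,(F:0.1,G:0.1):0.1):0.1):0.1);"
        )
        sp = parse_newick(newick, "species_tree")
        taxa = TaxonSet(tuple(sorted(sp.tip_labels())))
        truth = species_tree_from_genetree(sp, taxa)
        for seed in (1, 2, 3):
            cfg = SimulationConfig(
                n_taxa=7, n_genes=100, discordance=0.1, topo_moves=1,
                length_noise_sd=0.3, artifact_fraction=0.0, seed=seed,
            )
            trees, _ = simulate_gene_trees(sp, cfg)
            res = exhaustive_search(build_matrix(trees, taxa))
            assert len(res.best_trees) == 1
            assert res.best_trees[0] == truth


class TestHeuristicSearch:
    def test_identical_characters_recover_topology(self, worked_tree, abcd):
        m = build_matrix([worked_tree.clone() for _ in range(4)], TaxonSet(abcd))
        for seed in (0, 1, 2):
            res = heuristic_search(m, n_starts=2, seed=seed)
            assert res.best_trees[0].taxon_splits() == frozenset(
                {frozenset({"C", "D"})}
            )

    def test_deterministic_given_seed(self, small_simulation):
        sp, trees, labels, taxa = small_simulation
        m = build_matrix(trees[:25], taxa)
        a = heuristic_search(m, n_starts=3, seed=9)
        b = heuristic_search(m, n_starts=3, seed=9)
        assert a.score == b.score and a.evaluated == b.evaluated
        assert [t.splits() for t in a.best_trees] == [t.splits() for t in b.best_trees]

    @pytest.mark.parametrize("swap", ["NNI", "SPR", "TBR"])
    def test_never_beats_exhaustive_and_usually_matches(
        self, small_simulation, swap
    ):
        sp, trees, labels, taxa = small_simulation
        m = build_matrix(trees[:30], taxa)
        exact = exhaustive_search(m).score
        res = heuristic_search(m, n_starts=10, swap=swap, seed=3)
        assert res.score >= exact - 1e-9
        assert res.score == pytest.approx(exact, abs=1e-9)

    def test_bad_swap_rejected(self, small_simulation):
        sp, trees, labels, taxa = small_simulation
        m = build_matrix(trees[:5], taxa)
        with pytest.raises(ValueError, match="swap"):
            heuristic_search(m, swap="XYZ")


class TestBootstrap:
    def test_unanimous_matrix_gives_full_support(self, worked_tree, abcd):
        m = build_matrix([worked_tree.clone() for _ in range(5)], TaxonSet(abcd))
        bs = bootstrap(m, replicates=50, seed=0)
        assert bs.clade_support[frozenset({"C", "D"})] == pytest.approx(100.0)

    def test_single_replicate_support_values(self, small_simulation):
        sp, trees, labels, taxa = small_simulation
        m = build_matrix(trees[:12], taxa)
        bs = bootstrap(m, replicates=1, seed=1)
        for v in bs.clade_support.values():
            assert 0.0 < v <= 100.0

    def test_deterministic_and_search_paths_agree(self, worked_tree, abcd):
        m = build_matrix([worked_tree.clone() for _ in range(5)], TaxonSet(abcd))
        a = bootstrap(m, replicates=20, seed=7)
        b = bootstrap(m, replicates=20, seed=7)
        assert a.clade_support == b.clade_support
        h = bootstrap(
            m, replicates=20, seed=7,
            search=SearchConfig(method="heuristic", n_starts=2),
        )
        assert h.clade_support[frozenset({"C", "D"})] == pytest.approx(100.0)

    def test_discordance_lowers_support(self):
        sp = simulate_species_tree(7, seed=21)
        taxa = TaxonSet(tuple(sorted(sp.tip_labels())))
        cfg = SimulationConfig(
            n_taxa=7, n_genes=80, discordance=0.6, topo_moves=2,
            length_noise_sd=0.3, artifact_fraction=0.0, seed=21,
        )
        trees, _ = simulate_gene_trees(sp, cfg)
        m = build_matrix(trees, taxa)
        bs = bootstrap(m, replicates=200, seed=21)
        truth = species_tree_from_genetree(sp, taxa)
        supports = [bs.clade_support.get(s, 0.0) for s in truth.taxon_splits()]
        assert min(supports) < 100.0


class TestConsensusOfResults:
    def test_strict_consensus_of_ties(self, abcd):
        g1 = parse_newick("((A:1,B:1):1,(C:1,D:1):1);", "g1")
        g2 = parse_newick("((A:1,C:1):1,(B:1,D:1):1);", "g2")
        res = exhaustive_search(build_matrix([g1, g2], TaxonSet(abcd)))
        cons = consensus(res.best_trees, "strict")
        assert cons.taxon_splits() == frozenset()
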