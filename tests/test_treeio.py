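"""Gene-tree parsing, validation, rooting, filtering and distances."""

import itertools

import numpy as np
import pytest

from genechar import (
    TaxonSet,
    bipartitions,
    filter_long_branch,
    max_branch_length,
    parse_newick,
    patristic_matrix,
    root_on_outgroup,
)
from genechar.treeio import clusters, read_trees, removal_report, write_trees

from conftest import WORKED_DISTANCES, random_gene_tree


class TestParseNewick:
    def test_two_tip_tree(self):
        t = parse_newick("(A:1,B:1);")
        assert sorted(t.tip_labels()) == ["A", "B"]
        assert t.total_length() == 2.0

    def test_four_tip_structure(self, worked_tree):
        assert sorted(worked_tree.tip_labels()) == ["A", "B", "C", "D"]
        # the single non-trivial split of the hand-checked topology
        assert bipartitions(worked_tree) == frozenset({frozenset({"C", "D"})})

    def test_polytomy_preserved(self):
        t = parse_newick("(A:1,B:1,C:1);")
        assert len(t.tip_labels()) == 3
        assert bipartitions(t) == frozenset()

    def test_malformed_raises(self):
        with pytest.raises(ValueError, match="malformed"):
            parse_newick("((A:1,B:1;")

    def test_duplicate_tip_raises(self):
        with pytest.raises(ValueError):
            parse_newick("((A:1,A:1):1,B:1);")

    def test_missing_lengths_default_zero_with_warning(self):
        with pytest.warns(UserWarning, match="defaulted to 0"):
            t = parse_newick("((A,B),C);")
        assert t.total_length() == 0.0

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            parse_newick("(A:-1,B:1);")


class TestMaxBranchAndFilter:
    def test_max_of_listed_values(self, worked_tree):
        assert max_branch_length(worked_tree) == 2.0

    def test_zero_tree(self):
        assert max_branch_length(parse_newick("(A:0,B:0);")) == 0.0

    def test_single_long_edge(self):
        t = parse_newick("((A:0.1,B:1.6):0.2,(C:0.3,D:0.1):0.2);")
        assert max_branch_length(t) == 1.6

    def test_threshold_is_strict(self):
        trees = [
            parse_newick("(A:1.6,B:0.1);", "long"),
            parse_newick("(A:1.5,B:0.1);", "exact"),
            parse_newick("(A:0.3,B:0.1);", "short"),
        ]
        kept, removed = filter_long_branch(trees, 1.5)
        assert [t.gene_id for t in kept] == ["exact", "short"]
        assert [t.gene_id for t in removed] == ["long"]

    def test_empty_input(self):
        assert filter_long_branch([], 1.5) == ([], [])

    def test_counts_conserved_and_order_preserved(self):
        rng = np.random.default_rng(7)
        trees = [random_gene_tree(rng, 5) for _ in range(20)]
        kept, removed = filter_long_branch(trees, 0.25)
        assert len(kept) + len(removed) == len(trees)
        ids = iter(t.gene_id for t in trees)
        # merged streams preserve relative order of the input
        ki, ri = iter(kept), iter(removed)
        for t in trees:
            nxt = next(ki if t in kept else ri)
            assert nxt is t

    def test_report_flags(self):
        trees = [parse_newick("(A:2,B:0.1);", "x"), parse_newick("(A:1,B:1);", "y")]
        rep = removal_report(trees, 1.5)
        assert "x\t2\t1" in rep and "y\t1\t0" in rep


class TestPatristic:
    def test_worked_distances(self, worked_tree):
        dm = patristic_matrix(worked_tree)
        for (a, b), want in WORKED_DISTANCES.items():
            assert dm[(a, b)] == pytest.approx(want, abs=1e-12)

    def test_two_tips(self):
        assert patristic_matrix(parse_newick("(A:1,B:1);"))[("A", "B")] == 2.0

    def test_root_invariance(self, worked_tree):
        before = patristic_matrix(worked_tree)
        after = patristic_matrix(root_on_outgroup(worked_tree, "C"))
        assert before.labels == after.labels
        np.testing.assert_allclose(before.d, after.d, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_four_point_condition(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_gene_tree(rng, 6)
        dm = patristic_matrix(tree)
        d = dm.d
        for i, j, k, l in itertools.combinations(range(len(dm.labels)), 4):
            sums = sorted([d[i, j] + d[k, l], d[i, k] + d[j, l], d[i, l] + d[j, k]])
            assert sums[2] - sums[1] <= 1e-9


class TestRooting:
    def test_outgroup_rooting_recovers_clusters(self):
        t = parse_newick("((A:1,B:1):1,(C:1,O:1):1);")
        rooted = root_on_outgroup(t, "O")
        assert frozenset({"A", "B"}) in clusters(rooted)
        assert frozenset({"A", "B", "C"}) in clusters(rooted)

    def test_total_length_conserved(self):
        t = parse_newick("((A:1,B:1):1,(C:1,O:1):1);")
        assert root_on_outgroup(t, "O").total_length() == pytest.approx(
            t.total_length()
        )

    def test_two_tip_rooting(self):
        t = parse_newick("(A:1,B:1);")
        r = root_on_outgroup(t, "A")
        assert sorted(r.tip_labels()) == ["A", "B"]
        assert r.total_length() == pytest.approx(2.0)

    def test_missing_outgroup_named_in_error(self):
        with pytest.raises(ValueError, match="Frog"):
            root_on_outgroup(parse_newick("(A:1,B:1);"), "Frog")

    def test_split_set_unchanged_by_rooting(self):
        rng = np.random.default_rng(3)
        t = random_gene_tree(rng, 6)
        og = sorted(t.tip_labels())[0]
        assert bipartitions(t) == bipartitions(root_on_outgroup(t, og))


class TestBipartitions:
    def test_single_internal_edge(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert bipartitions(t) == frozenset({frozenset({"C", "D"})})

    def test_star_has_none(self):
        assert bipartitions(parse_newick("(A:1,B:1,C:1,D:1);")) == frozenset()

    def test_five_taxon_count(self):
        t = parse_newick("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")
        assert len(bipartitions(t)) == 2


class TestIO:
    def test_file_roundtrip(self, tmp_path):
        trees = [parse_newick("((A:1,B:1):1,C:1);", "g1"),
                 parse_newick("(A:1,(B:1,C:2):1);", "g2")]
        p = tmp_path / "trees.nwk"
        write_trees(trees, p)
        back = read_trees(p)
        assert [t.gene_id for t in back] == ["g000001", "g000002"]
        assert bipartitions(back[0]) == bipartitions(trees[0])

    def test_directory_input_uses_stems(self, tmp_path):
        (tmp_path / "alpha.nwk").write_text("(A:1,B:1);\n")
        (tmp_path / "beta.nwk").write_text("(A:2,B:2);\n")
        back = read_trees(tmp_path)
        assert [t.gene_id for t in back] == ["alpha", "beta"]
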