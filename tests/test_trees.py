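import numpy as np
import pandas as pd
import pytest

from isolocal.errors import (
    DegenerateInputError,
    EnsembleMismatchError,
    TreeFormatError,
    UnknownSpeciesError,
)
from isolocal.trees import (
    PDCalculator,
    PhyloTree,
    ScoreTable,
    TreeEnsemble,
    average_pairwise_apd,
    community_score_table,
    fair_proportion_ed,
    faith_pd,
    median_scores,
    patristic_matrix,
    pendant_edge_pe,
    prune_to_community,
    read_score_tables,
    read_trees,
    write_score_tables,
    write_trees,
)

from .conftest import random_tree


class TestReadTrees:
    def test_single_newick(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((A:1,B:1):1,C:2);\n")
        ens = read_trees(str(path))
        assert len(ens) == 1
        assert set(ens.tip_labels) == {"A", "B", "C"}
        assert ens[0].total_length() == 5.0

    def test_multi_tree_file(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((A:1,B:1):1,C:2);\n((A:2,B:2):1,C:3);\n")
        assert len(read_trees(str(path))) == 2

    def test_tip_set_mismatch_lists_difference(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((A:1,B:1):1,C:2);\n((A:1,B:1):1,D:2);\n")
        with pytest.raises(EnsembleMismatchError, match=r"C.*D|'C', 'D'"):
            read_trees(str(path))

    def test_parse_failure(self, tmp_path):
        path = tmp_path / "bad.nwk"
        path.write_text("((A:1,B:1:1,C:2);\n")
        with pytest.raises(TreeFormatError):
            read_trees(str(path))

    def test_quoted_labels_roundtrip(self, tmp_path):
        tree = PhyloTree.from_newick("(('sp one':1,sp_two:1):1,C:2);")
        assert "sp one" in tree.tip_labels and "sp_two" in tree.tip_labels
        path = tmp_path / "rt.nwk"
        write_trees([tree], str(path))
        again = read_trees(str(path))[0]
        assert sorted(again.tip_labels) == sorted(tree.tip_labels)
        assert again.total_length() == pytest.approx(tree.total_length())


class TestWorkedExample:
    """Hand-derived values on ((A:1,B:1):1,C:2);"""

    def test_ed(self, abc_tree):
        assert fair_proportion_ed(abc_tree).to_dict() == {
            "A": 1.5, "B": 1.5, "C": 2.0
        }

    def test_pe(self, abc_tree):
        assert pendant_edge_pe(abc_tree).to_dict() == {"A": 1.0, "B": 1.0, "C": 2.0}

    def test_patristic(self, abc_tree):
        D = patristic_matrix(abc_tree)
        assert D.loc["A", "B"] == 2.0
        assert D.loc["A", "C"] == 4.0
        assert D.loc["B", "C"] == 4.0
        assert (np.diag(D.values) == 0).all()

    def test_apd(self, abc_tree):
        assert average_pairwise_apd(abc_tree).to_dict() == {
            "A": 3.0, "B": 3.0, "C": 4.0
        }

    @pytest.mark.parametrize(
        "species,expected",
        [({"A", "B"}, 3.0), ({"A", "C"}, 4.0), ({"A", "B", "C"}, 5.0)],
    )
    def test_faith_pd(self, abc_tree, species, expected):
        assert faith_pd(abc_tree, species) == expected

    def test_star_tree_identities(self):
        star = PhyloTree.from_newick("(A:2,B:2,C:2);")
        ed = fair_proportion_ed(star)
        pe = pendant_edge_pe(star)
        assert (ed == 2.0).all()
        pd.testing.assert_series_equal(ed, pe, check_names=False)
        # equal pendant b on n tips: APD = 2b everywhere
        assert (average_pairwise_apd(star) == 4.0).all()


class TestFaithPD:
    def test_unknown_label_named(self, abc_tree):
        with pytest.raises(UnknownSpeciesError, match="Z"):
            faith_pd(abc_tree, {"A", "Z"})

    def test_empty_set(self, abc_tree):
        with pytest.raises(DegenerateInputError):
            faith_pd(abc_tree, set())

    def test_monotone_in_set(self):
        tree = random_tree(7, n_min=6, n_max=8)
        labels = tree.tip_labels
        prev = 0.0
        for i in range(1, len(labels) + 1):
            cur = faith_pd(tree, labels[:i])
            assert cur >= prev - 1e-12
            prev = cur

    def test_mrca_rooted_variant(self, abc_tree):
        assert faith_pd(abc_tree, {"A", "B"}, rooted=False) == 2.0
        assert faith_pd(abc_tree, {"A"}, rooted=False) == 0.0
        assert faith_pd(abc_tree, {"A", "B", "C"}, rooted=False) == 5.0


class TestPrune:
    def test_prune_pair_collapses_path(self, abc_tree):
        pruned = prune_to_community(abc_tree, {"A", "C"})
        assert sorted(pruned.tip_labels) == ["A", "C"]
        assert pruned.total_length() == 4.0
        assert pendant_edge_pe(pruned).to_dict() == {"A": 2.0, "C": 2.0}

    def test_prune_keeps_root_path(self, abc_tree):
        pruned = prune_to_community(abc_tree, {"A", "B"})
        assert pruned.total_length() == 3.0  # rooted convention

    def test_prune_full_set_is_identity(self, abc_tree):
        pruned = prune_to_community(abc_tree, {"A", "B", "C"})
        assert pruned.total_length() == abc_tree.total_length()
        assert fair_proportion_ed(pruned).to_dict() == fair_proportion_ed(
            abc_tree
        ).to_dict()

    def test_too_few_matching_tips(self, abc_tree):
        with pytest.raises(DegenerateInputError):
            prune_to_community(abc_tree, {"A"})

    @pytest.mark.parametrize("seed", range(25))
    def test_pruned_length_equals_faith_pd(self, seed):
        tree = random_tree(seed, n_min=4, n_max=8)
        rng = np.random.default_rng(seed + 1000)
        labels = tree.tip_labels
        size = int(rng.integers(2, len(labels) + 1))
        subset = set(rng.choice(labels, size=size, replace=False))
        pruned = prune_to_community(tree, subset)
        assert pruned.total_length() == pytest.approx(
            faith_pd(tree, subset), rel=1e-12
        )


class TestMedianScores:
    def test_single_tree_identity(self, abc_tree):
        ens = TreeEnsemble([abc_tree])
        pd.testing.assert_series_equal(
            median_scores(ens, "ED"), fair_proportion_ed(abc_tree),
            check_names=False,
        )

    def test_even_count_midpoint(self):
        t1 = PhyloTree.from_newick("((A:1,B:1):1,C:2);")
        t2 = PhyloTree.from_newick("((A:3,B:3):3,C:6);")
        med = median_scores(TreeEnsemble([t1, t2]), "ED")
        assert med["A"] == (1.5 + 4.5) / 2
        assert med["C"] == (2.0 + 6.0) / 2

    def test_replicated_tree(self, abc_tree):
        ens = TreeEnsemble([abc_tree, abc_tree.copy(), abc_tree.copy()])
        assert median_scores(ens, "APD").to_dict() == {"A": 3.0, "B": 3.0, "C": 4.0}


class TestScoreTable:
    def test_csv_roundtrip(self, tmp_path, abc_tree):
        table = ScoreTable.from_tree(abc_tree)
        path = tmp_path / "scores.csv"
        write_score_tables([table], str(path))
        back = read_score_tables(str(path))["GLOBAL"]
        pd.testing.assert_frame_equal(back.scores, table.scores)

    def test_community_scores_on_full_pool_match_global(self, abc_tree):
        ens = TreeEnsemble([abc_tree])
        local = community_score_table(ens, {"A", "B", "C"}, "c1")
        glob = ScoreTable.from_ensemble(ens)
        pd.testing.assert_frame_equal(
            local.scores.sort_index(), glob.scores.sort_index()
        )


class TestPDCalculator:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_faith_pd(self, seed):
        tree = random_tree(seed, n_min=3, n_max=8)
        calc = PDCalculator(tree)
        rng = np.random.default_rng(seed)
        labels = tree.tip_labels
        for _ in range(5):
            size = int(rng.integers(1, len(labels) + 1))
            subset = list(rng.choice(labels, size=size, replace=False))
            assert calc.pd(subset) == pytest.approx(faith_pd(tree, subset))

    def test_batch_agrees_with_scalar(self):
        tree = random_tree(3, n_min=5, n_max=8)
        calc = PDCalculator(tree)
        rng = np.random.default_rng(0)
        S = rng.random((len(calc.labels), 20)) < 0.5
        batch = calc.pd_batch(S)
        for r in range(20):
            subset = [calc.labels[i] for i in np.flatnonzero(S[:, r])]
            expected = calc.pd(subset) if subset else 0.0
            assert batch[r] == pytest.approx(expected)


def test_degenerate_single_tip():
    tree = PhyloTree.from_newick("(A:1);")
    with pytest.raises(DegenerateInputError):
        fair_proportion_ed(tree)
    with pytest.raises(DegenerateInputError):
        average_pairwise_apd(tree)


def test_read_nexus_trees_block(tmp_path):
    path = tmp_path / "trees.nex"
    path.write_text(
        "#NEXUS\nBEGIN TAXA;\nDIMENSIONS NTAX=3;\nTAXLABELS A B C;\nEND;\n"
        "BEGIN TREES;\nTREE t1 = ((A:1,B:1):1,C:2);\n"
        "TREE t2 = ((A:2,B:2):1,C:3);\nEND;\n"
    )
    ens = read_trees(str(path), format="nexus")
    assert len(ens) == 2
    assert sorted(ens.tip_labels) == ["A", "B", "C"]
    assert ens[0].total_length() == 5.0


def test_zero_length_pendant_edges_allowed():
    tree = PhyloTree.from_newick("((A:0,B:1):1,C:2);")
    assert pendant_edge_pe(tree)["A"] == 0.0
    ed = fair_proportion_ed(tree)
    assert ed.sum() == pytest.approx(tree.total_length())
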