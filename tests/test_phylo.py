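"""Distance matrices, NJ inversion, placement, and clock dating."""

import math

import dendropy
import numpy as np
import pytest

from gekkota.phylo import (
    CalibrationPoint, ReferenceSeq, classify_by_placement, date_expansions,
    fit_rate, neighbor_joining, node_depth, p_distance, pairwise_distance,
    read_calibrations, read_tree, write_tree,
)
from gekkota.simulate import make_clock_tree


def patristic(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    labels = sorted(taxa)
    return {
        (a, b): pdm.patristic_distance(taxa[a], taxa[b])
        for a in labels for b in labels if a < b
    }


class TestDistances:
    def test_identical_pair_is_zero(self):
        assert p_distance("ACGT", "ACGT") == 0.0

    def test_p_distance_counts_mismatches_with_pairwise_deletion(self):
        # 2 mismatches over 10 compared sites; gap column excluded
        assert p_distance("AAAAAAAAAA-", "AAAAAAAACCG") == pytest.approx(0.2)

    def test_poisson_correction(self):
        seqs = [("a", "AAAAAAAAAA"), ("b", "AAAAAAAACC")]
        _, mat = pairwise_distance(seqs, model="poisson")
        assert mat[0, 1] == pytest.approx(-math.log(0.8), abs=1e-4)

    def test_poisson_saturation_errors(self):
        with pytest.raises(ValueError, match="saturated"):
            pairwise_distance([("a", "AAAA"), ("b", "CCCC")], model="poisson")


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        # d(AB)=2, d(AC)=4, d(BC)=4 -> a=1, b=1, c=3
        mat = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = neighbor_joining(["A", "B", "C"], mat)
        dists = patristic(tree)
        assert dists[("A", "B")] == pytest.approx(2.0, abs=1e-9)
        assert dists[("A", "C")] == pytest.approx(4.0, abs=1e-9)
        assert dists[("B", "C")] == pytest.approx(4.0, abs=1e-9)

    def test_additive_matrix_inverted_exactly(self):
        # additive (here ultrametric) 5-taxon matrices from random clock trees
        rng = np.random.default_rng(5)
        for _ in range(10):
            ages = sorted(rng.uniform(10, 150, size=4), reverse=True)
            true = make_clock_tree(ages, rate=0.002)
            true_d = patristic(true)
            labels = sorted({a for pair in true_d for a in pair})
            n = len(labels)
            mat = np.zeros((n, n))
            for (a, b), d in true_d.items():
                i, j = labels.index(a), labels.index(b)
                mat[i, j] = mat[j, i] = d
            recovered = neighbor_joining(labels, mat)
            rec_d = patristic(recovered)
            for pair, d in true_d.items():
                assert rec_d[pair] == pytest.approx(d, abs=1e-9)

    def test_midpoint_root_of_ultrametric_matrix_is_true_root(self):
        true = make_clock_tree([100.0, 60.0, 30.0], rate=0.002)
        true_d = patristic(true)
        labels = sorted({a for pair in true_d for a in pair})
        n = len(labels)
        mat = np.zeros((n, n))
        for (a, b), d in true_d.items():
            i, j = labels.index(a), labels.index(b)
            mat[i, j] = mat[j, i] = d
        tree = neighbor_joining(labels, mat)
        # root-to-tip distances all equal under the recovered midpoint root
        depths = []
        for leaf in tree.leaf_node_iter():
            d, cur = 0.0, leaf
            while cur.parent_node is not None:
                d += cur.edge.length or 0.0
                cur = cur.parent_node
            depths.append(d)
        assert max(depths) - min(depths) < 1e-9


class TestPlacement:
    REFS = [
        ReferenceSeq("r1", "alpha", "ACGTACGTACGTACGTACGT"),
        ReferenceSeq("r2", "gamma", "ACGTACGTACGTTTTTTTTT"),
        ReferenceSeq("r3", "gamma", "ACGTACGTACGTTTTTTTTG"),
    ]

    def test_identical_to_reference(self):
        result = classify_by_placement(self.REFS[1].sequence, self.REFS)
        assert result.label == "gamma"
        assert result.distance == 0.0

    def test_equidistant_query_is_ambiguous(self):
        refs = [
            ReferenceSeq("a", "alpha", "AAAAAAAAAA"),
            ReferenceSeq("b", "beta", "CCCCAAAAAA"),
        ]
        result = classify_by_placement("CCAAAAAAAA", refs)  # 2 vs 2 mismatches
        assert result.label == "ambiguous"

    def test_slightly_evolved_query_keeps_label_with_margin(self):
        query = "ACGTACGTACGTACGTACGA"  # one step from the alpha reference
        result = classify_by_placement(query, self.REFS)
        assert result.label == "alpha"
        assert result.support > 0


class TestRateFitting:
    def test_single_calibration_ratio(self):
        tree = make_clock_tree([100.0], rate=0.005)
        cal = CalibrationPoint(frozenset({"T01", "T02"}), 100.0)
        assert fit_rate(tree, [cal]) == pytest.approx(0.005, rel=1e-12)

    def test_two_clocklike_calibrations_agree(self):
        tree = make_clock_tree([150.0, 80.0, 40.0], rate=0.003)
        leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
        cal_root = CalibrationPoint(frozenset(leaves), 150.0)
        cal_inner = CalibrationPoint(frozenset(leaves[1:]), 80.0)
        r_both = fit_rate(tree, [cal_root, cal_inner])
        assert fit_rate(tree, [cal_root]) == pytest.approx(r_both, rel=1e-9)
        assert fit_rate(tree, [cal_inner]) == pytest.approx(r_both, rel=1e-9)

    def test_known_rate_recovered_on_clocklike_tree(self):
        rate = 0.00217
        tree = make_clock_tree([120.0, 90.0, 55.0, 20.0], rate=rate)
        cal = CalibrationPoint(
            frozenset(l.taxon.label for l in tree.leaf_node_iter()), 120.0
        )
        assert fit_rate(tree, [cal]) == pytest.approx(rate, rel=1e-6)

    def test_interval_calibration_uses_midpoint(self):
        tree = make_clock_tree([58.5], rate=0.004)
        cal = CalibrationPoint(frozenset({"T01", "T02"}), (51.0, 66.0))
        assert fit_rate(tree, [cal]) == pytest.approx(0.004, rel=1e-9)

    def test_degenerate_calibration_errors(self):
        tree = make_clock_tree([100.0], rate=0.005)
        with pytest.raises(ValueError):
            CalibrationPoint(frozenset({"T01", "T02"}), 0.0)


class TestExpansionDating:
    AGES = [100.0, 98.0, 97.0, 85.0, 83.0]

    def _tree_and_rate(self, rate=0.002):
        tree = make_clock_tree(self.AGES, rate=rate)
        leaves = [l.taxon.label for l in tree.leaf_node_iter()]
        return tree, leaves

    def test_gap_five_splits_into_two_bursts(self):
        tree, leaves = self._tree_and_rate()
        report = date_expansions(tree, 0.002, leaves, max_gap=5.0)
        assert len(report.bursts) == 2
        (s1, e1, n1), (s2, e2, n2) = report.bursts
        assert (s1, e1, n1) == (pytest.approx(100.0), pytest.approx(97.0), 3)
        assert (s2, e2, n2) == (pytest.approx(85.0), pytest.approx(83.0), 2)
        assert not report.singletons

    def test_gap_twenty_merges_into_one_burst(self):
        tree, leaves = self._tree_and_rate()
        report = date_expansions(tree, 0.002, leaves, max_gap=20.0)
        assert len(report.bursts) == 1
        start, end, count = report.bursts[0]
        assert (start, end, count) == (pytest.approx(100.0), pytest.approx(83.0), 5)

    def test_scale_equivariance(self):
        tree1, leaves = self._tree_and_rate(rate=0.002)
        tree2, _ = self._tree_and_rate(rate=0.02)
        r1 = date_expansions(tree1, 0.002, leaves, max_gap=5.0)
        r2 = date_expansions(tree2, 0.02, leaves, max_gap=5.0)
        assert np.allclose(r1.ages, r2.ages)

    def test_ages_partition_into_bursts_and_singletons(self):
        tree = make_clock_tree([100.0, 98.0, 60.0, 20.0, 18.0], rate=0.002)
        leaves = [l.taxon.label for l in tree.leaf_node_iter()]
        report = date_expansions(tree, 0.002, leaves, max_gap=5.0)
        grouped = sum(n for _, _, n in report.bursts) + len(report.singletons)
        assert grouped == len(report.ages)
        assert report.singletons == (pytest.approx(60.0),)

    def test_single_member_clade_is_empty_report(self):
        tree, leaves = self._tree_and_rate()
        report = date_expansions(tree, 0.002, leaves[:1], max_gap=5.0)
        assert report.ages == () and report.bursts == ()


class TestTreeIO:
    def test_newick_roundtrip_preserves_lengths(self, tmp_path):
        tree = make_clock_tree([100.0, 42.5], rate=0.0031)
        path = tmp_path / "t.nwk"
        write_tree(tree, path)
        back = read_tree(path)
        orig = patristic(tree)
        again = patristic(back)
        for pair in orig:
            assert again[pair] == pytest.approx(orig[pair], rel=1e-5)

    def test_calibration_config_roundtrip(self, tmp_path):
        path = tmp_path / "cal.yaml"
        path.write_text(
            "- mrca: [A, B]\n  age: 156\n- mrca: [C, D]\n  age: [51, 66]\n"
        )
        cals = read_calibrations(path)
        assert cals[0].age == 156.0
        assert cals[1].age == (51.0, 66.0)
        assert cals[1].resolve_age() == pytest.approx(58.5)
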