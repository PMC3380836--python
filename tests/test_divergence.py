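"""p-distances, bootstrap variance, column partitioning, Kruskal-Wallis,
partition comparison, and neighbor joining."""

import io

import dendropy
import numpy as np
import pytest
from scipy import stats as sps

from ovolkit.core_io import AlignmentBlock, Interval
from ovolkit.disorder import RegionAnnotation
from ovolkit.divergence import (
    DistanceMatrix,
    bootstrap_variance,
    compare_partitions,
    distance_matrix,
    kruskal_wallis,
    nj_tree,
    p_distance,
    partition_columns,
)

AA = sorted("ACDEFGHIKLMNPQRSTVWY")


class TestPDistance:
    @pytest.mark.parametrize(
        "a,b,cols,expected",
        [
            ("ACDE", "ACDF", None, (0.25, 4)),
            ("AC-EF", "ACDEF", None, (0.0, 4)),
            ("ACDE", "ACDE", None, (0.0, 4)),
            ("AXDE", "AADE", None, (0.0, 3)),  # X excluded like a gap
            ("AAAA", "TTTT", [1, 2], (1.0, 2)),
        ],
    )
    def test_examples(self, a, b, cols, expected):
        d, n = p_distance(a, b, cols)
        assert (d, n) == expected

    def test_undefined_when_no_comparable_sites(self):
        d, n = p_distance("--", "AA")
        assert np.isnan(d) and n == 0

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError):
            p_distance("AA", "AAA")

    def test_metric_premises_on_random_rows(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 30))
            a = "".join(rng.choice(AA + ["-"], size=n))
            b = "".join(rng.choice(AA + ["-"], size=n))
            dab, _ = p_distance(a, b)
            dba, _ = p_distance(b, a)
            if not np.isnan(dab):
                assert dab == dba and 0.0 <= dab <= 1.0
            daa, naa = p_distance(a, a)
            if naa:
                assert daa == 0.0

    def test_column_subset_equals_subalignment(self, rng):
        block = AlignmentBlock(
            ["a", "b"],
            ["".join(rng.choice(AA + ["-"], size=40)) for _ in range(2)],
        )
        cols = sorted(rng.choice(np.arange(1, 41), size=15, replace=False).tolist())
        direct = p_distance(block.rows[0], block.rows[1], cols)
        sub = block.subset_columns(cols)
        assert direct == p_distance(sub.rows[0], sub.rows[1])


class TestDistanceMatrix:
    def test_identical_rows_all_zero(self):
        dm = distance_matrix(AlignmentBlock(list("abc"), ["ACDE"] * 3))
        assert np.allclose(dm.values, 0.0)
        assert dm.overall_mean() == 0.0

    def test_hand_enumerated_triple(self, tiny_block):
        dm = distance_matrix(tiny_block)
        assert dm.pair("a", "b") == 0.25
        assert dm.pair("a", "c") == 1.0
        assert dm.pair("b", "c") == 0.75
        assert dm.overall_mean() == pytest.approx(2 / 3)

    def test_symmetry_on_random_blocks(self, rng):
        for _ in range(20):
            rows = ["".join(rng.choice(AA + ["-"], size=25)) for _ in range(4)]
            dm = distance_matrix(AlignmentBlock(list("abcd"), rows))
            assert np.array_equal(dm.values, dm.values.T, equal_nan=True)
            assert np.all(np.diag(dm.values) == 0.0)


class TestBootstrapVariance:
    def test_identical_rows_variance_zero(self):
        block = AlignmentBlock(["a", "b"], ["ACDEACDE", "ACDEACDE"])
        var, kept = bootstrap_variance(block, ("a", "b"), 100, seed=5)
        assert var == 0.0 and kept == 100

    def test_deterministic_for_fixed_seed(self, tiny_block):
        v1, _ = bootstrap_variance(tiny_block, ("a", "b"), 500, seed=3)
        v2, _ = bootstrap_variance(tiny_block, ("a", "b"), 500, seed=3)
        assert v1 == v2

    def test_matches_binomial_theory(self):
        # d* = k/4 with k ~ Binomial(4, 1/4): Var = p(1-p)/4 = 0.046875
        block = AlignmentBlock(["a", "b"], ["AAAA", "AAAT"])
        var, kept = bootstrap_variance(block, ("a", "b"), 10000, seed=3)
        assert kept == 10000
        p = 0.25
        theory = p * (1 - p) / 4
        # standard error of the sample variance from exact binomial moments
        k = np.arange(5)
        pmf = sps.binom.pmf(k, 4, p)
        x = k / 4
        mu = float((pmf * x).sum())
        mu4 = float((pmf * (x - mu) ** 4).sum())
        se = np.sqrt((mu4 - theory**2 * (10000 - 3) / (10000 - 1)) / 10000)
        assert abs(var - theory) < 3 * se


class TestPartitionColumns:
    def _block(self):
        return AlignmentBlock(list("abcd"), ["AAAA", "AAAA", "AA-A", "AAAA"])

    def test_everything_annotated_disordered(self):
        block = AlignmentBlock(list("ab"), ["AAAA", "AAAA"])
        anns = [RegionAnnotation(i, Interval(1, 4), "disordered") for i in "ab"]
        block = AlignmentBlock(list("abc"), ["AAAA"] * 3)
        anns = [RegionAnnotation(i, Interval(1, 4), "disordered") for i in "abc"]
        structured, disordered = partition_columns(block, anns)
        assert structured == [] and disordered == [1, 2, 3, 4]

    def test_no_annotations_all_structured(self):
        structured, disordered = partition_columns(self._block(), [])
        assert disordered == [] and structured == [1, 2, 3, 4]

    def test_majority_vote_with_gap(self):
        # column 3: row c is gapped; rows a,b annotated there -> 2 of 3
        # non-gap residues disordered > 0.5
        anns = [
            RegionAnnotation("a", Interval(3, 3), "disordered"),
            RegionAnnotation("b", Interval(3, 3), "disordered"),
        ]
        structured, disordered = partition_columns(self._block(), anns, 0.5)
        assert disordered == [3]

    def test_unknown_row_is_error(self):
        with pytest.raises(ValueError, match="unknown row"):
            partition_columns(self._block(), [RegionAnnotation("zz", Interval(1, 2), "disordered")])


class TestKruskalWallis:
    def test_textbook_no_tie_case(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.H == pytest.approx(7.2)
        assert res.df == 2
        assert res.tie_correction == 1.0
        assert res.p_value == pytest.approx(float(sps.chi2.sf(7.2, 2)))

    def test_fully_tied_groups(self):
        res = kruskal_wallis([[1, 2], [1, 2]])
        assert res.H == pytest.approx(0.0)
        assert res.tie_correction == pytest.approx(0.8)

    def test_all_identical_values_h_zero(self):
        res = kruskal_wallis([[5, 5, 5], [5, 5, 5]])
        assert res.H == 0.0 and res.tie_correction == 0.0

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])

    def test_agrees_with_scipy_on_random_groups(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 5))
            groups = [
                rng.integers(0, 8, size=int(rng.integers(2, 8))).astype(float)
                for _ in range(k)
            ]
            if np.ptp(np.concatenate(groups)) == 0:
                continue  # scipy rejects all-identical input
            res = kruskal_wallis(groups)
            ref = sps.kruskal(*groups)
            assert res.H == pytest.approx(ref.statistic, rel=1e-10)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_permutation_p_is_seeded_and_consistent(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        r1 = kruskal_wallis(groups, permutation=500, seed=11)
        r2 = kruskal_wallis(groups, permutation=500, seed=11)
        assert r1.permutation_p == r2.permutation_p
        assert 0 < r1.permutation_p < 0.2


class TestComparePartitions:
    def test_fully_conserved_block(self):
        block = AlignmentBlock(list("abc"), ["ACDEACDE"] * 3)
        anns = [RegionAnnotation(i, Interval(1, 4), "disordered") for i in "abc"]
        pset, kw, box = compare_partitions(block, anns, seed=0)
        assert np.allclose(pset.full, 0) and np.allclose(pset.disordered, 0)
        assert kw.H == 0.0
        assert set(box["partition"]) == {"structured", "disordered", "full"}

    def test_randomized_disordered_half_near_saturation(self, rng):
        ncol, nrow = 400, 6
        conserved = "".join(rng.choice(AA, size=ncol // 2))
        rows = [
            conserved + "".join(rng.choice(AA, size=ncol // 2)) for _ in range(nrow)
        ]
        block = AlignmentBlock([f"t{i}" for i in range(nrow)], rows)
        anns = [
            RegionAnnotation(f"t{i}", Interval(ncol // 2 + 1, ncol), "disordered")
            for i in range(nrow)
        ]
        pset, kw, box = compare_partitions(block, anns, seed=0)
        med = box.set_index("partition")["median"]
        assert med["disordered"] == pytest.approx(1 - 1 / 20, abs=0.03)
        assert med["structured"] == 0.0
        assert kw.p_value < 0.01

    def test_empty_partition_flagged_and_kw_still_runs(self):
        block = AlignmentBlock(list("abc"), ["ACDE", "ACDF", "AGDE"])
        pset, kw, box = compare_partitions(block, [], seed=0)
        assert "disordered" in pset.empty_partitions
        assert kw is not None and kw.df == 1  # full vs structured

    def test_simulated_family_ordering(self, default_family):
        from ovolkit.disorder import call_disordered_regions
        from ovolkit.simulate import emit_disorder_tracks

        tracks = emit_disorder_tracks(default_family, 0.0, seed=0)
        anns = [a for tr in tracks.values() for a in call_disordered_regions(tr, 5)]
        pset, kw, box = compare_partitions(default_family.alignment, anns, seed=0)
        med = box.set_index("partition")["median"]
        assert med["disordered"] > med["structured"]

    def test_pairwise_rule_variant(self, default_family):
        from ovolkit.disorder import call_disordered_regions
        from ovolkit.simulate import emit_disorder_tracks

        tracks = emit_disorder_tracks(default_family, 0.0, seed=0)
        anns = [a for tr in tracks.values() for a in call_disordered_regions(tr, 5)]
        pset, kw, _ = compare_partitions(
            default_family.alignment, anns, seed=0, pair_rule="pairwise"
        )
        assert np.median(pset.disordered) > np.median(pset.structured)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def _random_additive_tree(rng, n_taxa):
    """Random binary topology with random positive branch lengths; returns
    (newick, taxon->taxon path-length distance matrix)."""
    nodes = [(f"t{i}", None) for i in range(n_taxa)]  # (newick, None)
    dists = {f"t{i}": {f"t{i}": 0.0} for i in range(n_taxa)}
    leaf_sets = [{f"t{i}"} for i in range(n_taxa)]
    newicks = [f"t{i}" for i in range(n_taxa)]
    depth = [{f"t{i}": 0.0} for i in range(n_taxa)]  # leaf -> dist to subtree root
    while len(newicks) > 1:
        i, j = sorted(rng.choice(len(newicks), size=2, replace=False).tolist())
        bi = float(rng.uniform(0.1, 2.0))
        bj = float(rng.uniform(0.1, 2.0))
        for la in leaf_sets[i]:
            for lb in leaf_sets[j]:
                d = depth[i][la] + bi + depth[j][lb] + bj
                dists[la][lb] = dists[lb][la] = d
        merged_leaves = leaf_sets[i] | leaf_sets[j]
        merged_depth = {la: depth[i][la] + bi for la in leaf_sets[i]}
        merged_depth.update({lb: depth[j][lb] + bj for lb in leaf_sets[j]})
        merged_newick = f"({newicks[i]}:{bi},{newicks[j]}:{bj})"
        for idx in (j, i):
            newicks.pop(idx)
            leaf_sets.pop(idx)
            depth.pop(idx)
        newicks.append(merged_newick)
        leaf_sets.append(merged_leaves)
        depth.append(merged_depth)
    return newicks[0] + ";", dists


def _rf_distance(newick_a, newick_b):
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(ta, tb)


def nj_from_pairwise(dists, taxa):
    n = len(taxa)
    values = np.array([[dists[a][b] for b in taxa] for a in taxa])
    return nj_tree(DistanceMatrix(list(taxa), values, np.ones((n, n), dtype=int)))


class TestNeighborJoining:
    def test_recovers_four_taxon_additive_tree_exactly(self):
        values = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        dm = DistanceMatrix(list("ABCD"), values, np.ones((4, 4), dtype=int))
        newick = nj_tree(dm)
        assert _rf_distance(newick, "((A:1,B:2):1,(C:3,D:4):0);") == 0
        # branch lengths recovered: total tree length is 1+2+1+3+4 = 11
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert sum(e.length for e in tree.edges() if e.length) == pytest.approx(11.0)

    def test_three_taxa_closed_form(self):
        values = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        dm = DistanceMatrix(list("ABC"), values, np.ones((3, 3), dtype=int))
        tree = dendropy.Tree.get(data=nj_tree(dm), schema="newick")
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx(0.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)

    def test_deterministic_on_ties(self):
        values = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(list("ABCD"), values, np.ones((4, 4), dtype=int))
        assert nj_tree(dm) == nj_tree(dm)

    def test_undefined_entries_rejected(self):
        values = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]])
        dm = DistanceMatrix(list("ABC"), values, np.ones((3, 3), dtype=int))
        with pytest.raises(ValueError, match="undefined"):
            nj_tree(dm)

    def test_recovers_random_additive_topologies(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 9))
            true_newick, dists = _random_additive_tree(rng, n)
            taxa = [f"t{i}" for i in range(n)]
            assert _rf_distance(nj_from_pairwise(dists, taxa), true_newick) == 0
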