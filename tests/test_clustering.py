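"""Correlation distance, from-scratch agglomeration, cluster extraction."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy as scipy_hierarchy
from scipy.spatial.distance import squareform

from oncoburden import (
    CohortSpec,
    CorrelationHierarchicalClustering,
    agglomerative_cluster,
    assign_patients,
    correlation_distance,
    extract_clusters,
    filter_rare_conditions,
    generate_patient_table,
)

from conftest import assert_same_merges, oracle_agglomerate


def random_distance_matrix(rng: np.random.Generator, k: int) -> pd.DataFrame:
    d = rng.random((k, k))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    labels = [f"c{i}" for i in range(k)]
    return pd.DataFrame(d, index=labels, columns=labels)


class TestRareFilter:
    def test_zero_count_column_dropped(self):
        m = pd.DataFrame({"a": [1, 1, 1], "b": [0, 0, 0]})
        out = filter_rare_conditions(m, min_count=3)
        assert list(out.columns) == ["a"]

    def test_boundary_exactly_min_count_retained(self):
        m = pd.DataFrame({"a": [1, 1, 1, 0], "b": [1, 1, 0, 0]})
        out = filter_rare_conditions(m, min_count=3)
        assert list(out.columns) == ["a"]
        out2 = filter_rare_conditions(m, min_count=2)
        assert list(out2.columns) == ["a", "b"]

    def test_all_dropped_errors(self):
        m = pd.DataFrame({"a": [0, 0], "b": [0, 1]})
        with pytest.raises(ValueError, match="no conditions remain"):
            filter_rare_conditions(m, min_count=3)

    def test_15_conditions_two_rare_leaves_13(self):
        rng = np.random.default_rng(5)
        base = CohortSpec()  # for the 15-condition roster names
        spec = CohortSpec(
            n_patients=400, seed=5,
            condition_prevalence={c: 0.2 for c in base.conditions})
        table = generate_patient_table(spec).set_index("patient_id")
        m = table[list(spec.conditions)].copy()
        # plant two rare columns, as when myocardial infarction and dementia
        # nearly vanish from a stratum
        m["myocardial_infarction"] = 0
        m["dementia"] = 0
        dem_idx = rng.choice(len(m), 2, replace=False)
        m.iloc[dem_idx, m.columns.get_loc("dementia")] = 1
        out = filter_rare_conditions(m, min_count=3)
        assert out.shape[1] == 13
        assert "myocardial_infarction" not in out.columns
        assert "dementia" not in out.columns


class TestCorrelationDistance:
    def test_identical_columns_distance_zero(self):
        m = pd.DataFrame({"a": [1, 0, 1, 0], "b": [1, 0, 1, 0]})
        d = correlation_distance(m)
        assert d.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_complementary_columns_distance_two(self):
        m = pd.DataFrame({"a": [1, 0, 1, 0], "b": [0, 1, 0, 1]})
        d = correlation_distance(m)
        assert d.loc["a", "b"] == pytest.approx(2.0, abs=1e-12)

    def test_toy_matrix_matches_direct_formula(self):
        m = pd.DataFrame({"a": [1, 1, 0, 0], "b": [1, 0, 1, 0],
                          "c": [1, 1, 1, 0]})
        d = correlation_distance(m)
        for x in m.columns:
            for y in m.columns:
                r = np.corrcoef(m[x], m[y])[0, 1]
                assert d.loc[x, y] == pytest.approx(1.0 - r, abs=1e-12)

    def test_zero_variance_column_errors_by_name(self):
        m = pd.DataFrame({"a": [1, 0, 1], "b": [1, 1, 1]})
        with pytest.raises(ValueError, match="b"):
            correlation_distance(m)

    def test_axioms_on_random_binary_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            m = pd.DataFrame(rng.integers(0, 2, size=(30, 5)),
                             columns=list("abcde"))
            m = m.loc[:, m.std() > 0]
            if m.shape[1] < 2:
                continue
            d = correlation_distance(m).to_numpy()
            assert np.allclose(d, d.T)
            assert np.allclose(np.diag(d), 0)
            assert (d >= -1e-12).all() and (d <= 2 + 1e-12).all()

    def test_sqrt_transform(self):
        m = pd.DataFrame({"a": [1, 0, 1, 0], "b": [0, 1, 0, 1]})
        d = correlation_distance(m, transform="sqrt")
        assert d.loc["a", "b"] == pytest.approx(2.0)  # sqrt(2*(1-(-1)))

    def test_permutation_equivariance_in_patients(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.integers(0, 2, size=(40, 4)),
                         columns=list("abcd"))
        d1 = correlation_distance(m)
        d2 = correlation_distance(m.sample(frac=1, random_state=7))
        pd.testing.assert_frame_equal(d1, d2)


class TestAgglomeration:
    @pytest.mark.parametrize("linkage", ["average", "complete", "single"])
    def test_two_leaves_single_merge(self, linkage):
        d = pd.DataFrame([[0.0, 0.4], [0.4, 0.0]],
                         index=["a", "b"], columns=["a", "b"])
        tree = agglomerative_cluster(d, linkage=linkage)
        assert len(tree.merges) == 1
        assert tree.merges[0].height == pytest.approx(0.4)

    @pytest.mark.parametrize("linkage", ["average", "complete", "single"])
    @pytest.mark.parametrize("k", [3, 4, 5, 6])
    def test_matches_bruteforce_oracle(self, linkage, k):
        rng = np.random.default_rng(100 * k)
        for _ in range(10):
            d = random_distance_matrix(rng, k)
            tree = agglomerative_cluster(d, linkage=linkage)
            assert_same_merges(tree, oracle_agglomerate(d, linkage))

    @pytest.mark.parametrize("linkage", ["average", "complete", "single"])
    def test_matches_scipy_heights(self, linkage):
        """Cross-check merge heights against the scipy implementation."""
        rng = np.random.default_rng(8)
        d = random_distance_matrix(rng, 7)
        tree = agglomerative_cluster(d, linkage=linkage)
        Z = scipy_hierarchy.linkage(squareform(d.to_numpy()), method=linkage)
        ours = sorted(m.height for m in tree.merges)
        theirs = sorted(Z[:, 2])
        assert np.allclose(ours, theirs)

    @pytest.mark.parametrize("linkage", ["average", "complete"])
    def test_heights_nondecreasing(self, linkage):
        rng = np.random.default_rng(21)
        d = random_distance_matrix(rng, 8)
        tree = agglomerative_cluster(d, linkage=linkage)
        heights = [m.height for m in tree.merges]
        assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    def test_tie_break_deterministic_lexicographic(self):
        labels = list("abcd")
        d = pd.DataFrame(1.0, index=labels, columns=labels)
        for lab in labels:
            d.loc[lab, lab] = 0.0
        tree = agglomerative_cluster(d, linkage="average")
        assert tree.merges[0].left == ("a",)
        assert tree.merges[0].right == ("b",)

    def test_invalid_matrix_rejected(self):
        bad = pd.DataFrame([[0.0, 1.0], [0.5, 0.0]],
                           index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="symmetric"):
            agglomerative_cluster(bad)
        neg = pd.DataFrame([[0.0, -0.2], [-0.2, 0.0]],
                           index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="non-negative"):
            agglomerative_cluster(neg)

    def test_condition_order_permutation_same_topology(self):
        rng = np.random.default_rng(13)
        m = pd.DataFrame(rng.integers(0, 2, size=(60, 5)),
                         columns=list("abcde"))
        d1 = correlation_distance(m)
        perm = list("cbead")
        d2 = correlation_distance(m[perm])
        t1 = agglomerative_cluster(d1)
        t2 = agglomerative_cluster(d2)
        sig1 = [frozenset((frozenset(x.left), frozenset(x.right)))
                for x in t1.merges]
        sig2 = [frozenset((frozenset(x.left), frozenset(x.right)))
                for x in t2.merges]
        assert sig1 == sig2

    def test_newick_export_parses(self):
        from Bio import Phylo

        rng = np.random.default_rng(2)
        d = random_distance_matrix(rng, 5)
        tree = agglomerative_cluster(d)
        parsed = Phylo.read(io.StringIO(tree.to_newick()), "newick")
        assert sorted(t.name for t in parsed.get_terminals()) == sorted(d.columns)


class TestExtractAndAssign:
    def _tree(self):
        d = pd.DataFrame(
            [[0.0, 0.2, 0.9, 0.95],
             [0.2, 0.0, 0.92, 0.9],
             [0.9, 0.92, 0.0, 0.3],
             [0.95, 0.9, 0.3, 0.0]],
            index=list("abcd"), columns=list("abcd"))
        return agglomerative_cluster(d)

    def test_cut_height_zero_all_singletons(self):
        groups = extract_clusters(self._tree(), height=0.0)
        assert groups == [("a",), ("b",), ("c",), ("d",)]

    def test_cut_two_leaf_tree_into_one(self):
        d = pd.DataFrame([[0.0, 0.4], [0.4, 0.0]],
                         index=["a", "b"], columns=["a", "b"])
        groups = extract_clusters(agglomerative_cluster(d), n_clusters=1)
        assert groups == [("a", "b")]

    def test_two_block_cut_recovers_planted_pairs(self):
        groups = extract_clusters(self._tree(), n_clusters=2)
        assert sorted(groups) == [("a", "b"), ("c", "d")]

    def test_too_many_clusters_errors(self):
        with pytest.raises(ValueError, match="n_clusters"):
            extract_clusters(self._tree(), n_clusters=5)

    def test_assignment_rules(self):
        matrix = pd.DataFrame(
            {"a": [0, 1, 1, 0], "b": [0, 1, 0, 0],
             "c": [0, 0, 1, 1], "d": [0, 0, 1, 1]},
            index=["p0", "p1", "p2", "p3"])
        cs = assign_patients([("a", "b"), ("c", "d")], matrix)
        by_label = {c.conditions: set(c.patient_ids) for c in cs.clusters}
        assert by_label[("a", "b")] == {"p1"}
        assert by_label[("c", "d")] == {"p2", "p3"}
        # p0 has nothing and belongs nowhere
        assert all("p0" not in c.patient_ids for c in cs.clusters)

    def test_exclusive_assignment_prefers_larger_cluster(self):
        matrix = pd.DataFrame(
            {"a": [1], "b": [1], "c": [1], "d": [1], "e": [1]},
            index=["p0"])
        cs = assign_patients([("a", "b"), ("c", "d", "e")], matrix,
                             exclusive=True)
        by_label = {c.conditions: set(c.patient_ids) for c in cs.clusters}
        assert by_label[("c", "d", "e")] == {"p0"}
        assert by_label[("a", "b")] == set()
        both = assign_patients([("a", "b"), ("c", "d", "e")], matrix,
                               exclusive=False)
        assert all(set(c.patient_ids) == {"p0"} for c in both.clusters)

    def test_overlapping_clusters_error(self):
        matrix = pd.DataFrame({"a": [1], "b": [1]}, index=["p0"])
        with pytest.raises(ValueError, match="overlap"):
            assign_patients([("a", "b"), ("a",  "b")], matrix)

    def test_membership_matches_bruteforce_scan(self):
        spec = CohortSpec(n_patients=800, seed=41)
        table = generate_patient_table(spec).set_index("patient_id")
        matrix = table[list(spec.conditions)]
        clusters = [("hypertension", "diabetes"),
                    ("mild_liver_disease", "renal_disease")]
        cs = assign_patients(clusters, matrix, exclusive=False)
        for cluster in cs.clusters:
            expected = {pid for pid, row in matrix.iterrows()
                        if all(row[c] == 1 for c in cluster.conditions)}
            assert set(cluster.patient_ids) == expected
            assert cluster.n == len(expected)


class TestEstimator:
    def test_planted_two_block_recovery_single_run(self):
        spec = CohortSpec(
            n_patients=5000, seed=71,
            condition_prevalence={"hypertension": 0.3, "diabetes": 0.3,
                                  "cerebrovascular_disease": 0.3,
                                  "peripheral_vascular_disease": 0.3},
            cooccurrence_blocks=[
                (("hypertension", "diabetes"), 0.6),
                (("cerebrovascular_disease",
                  "peripheral_vascular_disease"), 0.6)])
        table = generate_patient_table(spec).set_index("patient_id")
        est = CorrelationHierarchicalClustering(n_clusters=2, min_count=3)
        est.fit(table[list(spec.conditions)])
        got = {frozenset(c) for c in est.cluster_conditions_}
        assert got == {frozenset({"hypertension", "diabetes"}),
                       frozenset({"cerebrovascular_disease",
                                  "peripheral_vascular_disease"})}
        assert set(est.labels_.unique()) <= {
            "none", "diabetes-hypertension",
            "cerebrovascular_disease-peripheral_vascular_disease"}

    def test_sklearn_params_round_trip(self):
        est = CorrelationHierarchicalClustering(linkage="complete",
                                                n_clusters=3)
        params = est.get_params()
        clone = CorrelationHierarchicalClustering(**params)
        assert clone.get_params() == params
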