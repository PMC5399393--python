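import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from comorbidnet.comorbidity_clustering import (
    BinaryProfileMatrix,
    DissimilarityMatrix,
    bootstrap_stability,
    build_matrix,
    classical_mds,
    classify_stability,
    cut_tree,
    dissimilarity,
    hierarchical_cluster,
    jaccard_index,
    to_newick,
)
from comorbidnet.io_model import DisorderGeneTable
from comorbidnet.synthetic_data import SyntheticScenario, generate_disorder_tables

gene_sets = st.frozensets(st.sampled_from("ABCDEFGH"), min_size=1, max_size=8)


class TestJaccard:
    def test_counting_example(self):
        assert jaccard_index({"G1", "G2", "G3"}, {"G2", "G3", "G4"}) == 0.5

    @given(gene_sets)
    @settings(max_examples=50, derandomize=True)
    def test_identity(self, s):
        assert jaccard_index(s, s) == 1.0

    @given(gene_sets, gene_sets)
    @settings(max_examples=100, derandomize=True)
    def test_symmetric_bounded_and_one_iff_equal(self, a, b):
        j = jaccard_index(a, b)
        assert j == jaccard_index(b, a)
        assert 0.0 <= j <= 1.0
        assert (j == 1.0) == (a == b)

    def test_disjoint_sets(self):
        assert jaccard_index({"A"}, {"B"}) == 0.0

    def test_both_empty_undefined(self):
        with pytest.raises(ValueError):
            jaccard_index(set(), set())


class TestProfileMatrix:
    def test_enumeration(self):
        t = DisorderGeneTable({"D1": frozenset("AB"), "D2": frozenset("BC")}, focal="D1")
        m = build_matrix(t)
        assert m.df.shape == (2, 3)
        assert list(m.df.columns) == ["A", "B", "C"]
        assert m.df.sum(axis=1).tolist() == [2, 2]

    def test_identical_disorders_identical_rows(self):
        t = DisorderGeneTable({"D1": frozenset("AB"), "D2": frozenset("AB")}, focal="D1")
        m = build_matrix(t)
        assert (m.df.iloc[0] == m.df.iloc[1]).all()

    def test_single_disorder_rejected(self):
        with pytest.raises(ValueError):
            build_matrix(DisorderGeneTable({"D1": frozenset("A")}, focal="D1"))


class TestDissimilarity:
    def test_identical_and_disjoint_rows(self):
        t = DisorderGeneTable(
            {"D1": frozenset("AB"), "D2": frozenset("AB"), "D3": frozenset("XY")}, focal="D1"
        )
        d = dissimilarity(build_matrix(t))
        assert d.d[0, 1] == 0.0
        assert d.d[0, 2] == 1.0
        assert np.allclose(d.d, d.d.T)
        assert np.all(np.diag(d.d) == 0)

    def test_metric_axioms_on_random_families(self):
        """Jaccard distance satisfies the triangle inequality: brute-force check
        over random 5-disorder tables (100 seeds)."""
        rng = np.random.default_rng(0)
        universe = [f"G{i}" for i in range(10)]
        for _ in range(100):
            entries = {}
            for i in range(5):
                size = int(rng.integers(1, 10))
                entries[f"D{i}"] = frozenset(rng.choice(universe, size=size, replace=False))
            d = dissimilarity(build_matrix(DisorderGeneTable(entries, focal="D0"))).d
            assert (d >= 0).all() and (d <= 1).all()
            for i, j, k in itertools.permutations(range(5), 3):
                assert d[i, k] <= d[i, j] + d[j, k] + 1e-12


class TestHierarchicalClustering:
    def test_identical_profiles_merge_first_at_zero(self):
        t = DisorderGeneTable(
            {"D1": frozenset("AB"), "D2": frozenset("AB"), "D3": frozenset("CD")}, focal="D1"
        )
        tree = hierarchical_cluster(dissimilarity(build_matrix(t)))
        assert tree.linkage_matrix[0, 2] == 0.0
        assert set(tree.linkage_matrix[0, :2]) == {0.0, 1.0}

    def test_average_linkage_matches_hand_agglomeration(self):
        """Four-point toy distances: merge heights equal a brute-force UPGMA run."""
        labels = ["a", "b", "c", "d"]
        d = np.array(
            [
                [0.0, 0.10, 0.70, 0.85],
                [0.10, 0.0, 0.60, 0.75],
                [0.70, 0.60, 0.0, 0.30],
                [0.85, 0.75, 0.30, 0.0],
            ]
        )

        # independent oracle: naive agglomeration with average linkage
        clusters = [{i} for i in range(4)]
        dist = {(i, j): d[i, j] for i in range(4) for j in range(i + 1, 4)}
        heights = []
        while len(clusters) > 1:
            (bi, bj), h = min(
                (
                    ((i, j), sum(d[p, q] for p in clusters[i] for q in clusters[j])
                     / (len(clusters[i]) * len(clusters[j])))
                    for i in range(len(clusters))
                    for j in range(i + 1, len(clusters))
                ),
                key=lambda t: t[1],
            )
            heights.append(h)
            clusters = [c for k, c in enumerate(clusters) if k not in (bi, bj)] + [
                clusters[bi] | clusters[bj]
            ]

        tree = hierarchical_cluster(DissimilarityMatrix(labels, d), linkage="average")
        assert np.allclose(sorted(tree.linkage_matrix[:, 2]), sorted(heights), atol=1e-12)

    def test_unknown_linkage_rejected(self):
        t = DisorderGeneTable({"D1": frozenset("A"), "D2": frozenset("B")}, focal="D1")
        with pytest.raises(ValueError):
            hierarchical_cluster(dissimilarity(build_matrix(t)), linkage="ward")

    def test_newick_roundtrips_through_dendropy(self):
        import dendropy

        t = DisorderGeneTable(
            {"D1": frozenset("AB"), "D2": frozenset("AC"), "D3": frozenset("XY")}, focal="D1"
        )
        tree = hierarchical_cluster(dissimilarity(build_matrix(t)))
        parsed = dendropy.Tree.get(data=to_newick(tree), schema="newick")
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == {"D1", "D2", "D3"}


class TestCutTree:
    @pytest.fixture
    def tree(self, toy_tables):
        return hierarchical_cluster(dissimilarity(build_matrix(toy_tables)))

    def test_k_one_single_cluster(self, tree):
        assignment = cut_tree(tree, 1)
        assert set(assignment.labels.values()) == {0}

    def test_k_n_all_singletons(self, tree):
        assignment = cut_tree(tree, 4)
        assert len(set(assignment.labels.values())) == 4

    def test_partition_for_every_k(self, tree):
        for k in range(1, 5):
            assignment = cut_tree(tree, k)
            assert len(assignment.labels) == 4
            assert len(set(assignment.labels.values())) == k

    def test_k_out_of_range(self, tree):
        with pytest.raises(ValueError):
            cut_tree(tree, 0)
        with pytest.raises(ValueError):
            cut_tree(tree, 5)

    def test_recovers_planted_partition(self):
        sc = SyntheticScenario(
            n_groups=3, disorders_per_group=5, core_size=20, private_size=4,
            share_prob=1.0, n_planted_candidates=0, n_null_candidates=0, seed=5,
        )
        tables, truth = generate_disorder_tables(sc)
        tree = hierarchical_cluster(dissimilarity(build_matrix(tables)))
        assignment = cut_tree(tree, 3)
        recovered = {frozenset(assignment.members(c)) for c in range(3)}
        planted = {
            frozenset(d for d, g in truth.groups.items() if g == grp) for grp in range(3)
        }
        assert recovered == planted


class TestBootstrapStability:
    def test_b_below_one_rejected(self, toy_tables):
        with pytest.raises(ValueError):
            bootstrap_stability(build_matrix(toy_tables), k=2, B=0)

    def test_stabilities_bounded(self, toy_tables):
        report = bootstrap_stability(build_matrix(toy_tables), k=2, B=50, seed=1)
        assert all(0.0 <= s <= 1.0 for s in report.stability.values())
        assert set(report.stability) == set(report.clusters)

    def test_deterministic_given_seed(self, toy_tables):
        m = build_matrix(toy_tables)
        r1 = bootstrap_stability(m, k=2, B=30, seed=9)
        r2 = bootstrap_stability(m, k=2, B=30, seed=9)
        assert r1.stability == r2.stability


class TestClassifyStability:
    def test_threshold_bands(self):
        from comorbidnet.comorbidity_clustering import StabilityReport

        report = StabilityReport(
            B=10, seed=0,
            clusters={0: frozenset("A"), 1: frozenset("B"), 2: frozenset("C")},
            stability={0: 0.785, 1: 0.50, 2: 0.55},
            dissolved={0: 0, 1: 5, 2: 3},
        )
        labels = classify_stability(report)
        assert labels == {0: "stable", 1: "unstable", 2: "borderline"}


class TestClassicalMds:
    def test_all_zero_dissimilarity_maps_to_origin(self):
        d = DissimilarityMatrix(["a", "b", "c"], np.zeros((3, 3)))
        emb = classical_mds(d)
        assert np.allclose(emb.coords, 0.0)

    def test_planar_configuration_reproduced(self):
        pts = np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 1.5], [-0.5, 2.0]])
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        emb = classical_mds(DissimilarityMatrix(list("abcd"), d))
        d_emb = np.sqrt(((emb.coords[:, None, :] - emb.coords[None, :, :]) ** 2).sum(-1))
        assert np.allclose(d_emb, d, atol=1e-9)

    def test_eigenvalues_nonincreasing_and_coords_centered(self, toy_tables):
        emb = classical_mds(dissimilarity(build_matrix(toy_tables)))
        assert (np.diff(emb.eigenvalues) <= 1e-12).all()
        assert np.allclose(emb.coords.mean(axis=0), 0.0, atol=1e-12)

    def test_dims_exceeding_points_rejected(self):
        d = DissimilarityMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            classical_mds(d, dims=2)
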