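"""Family calling, the cluster network, and UPGMA dendrograms."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score
from sklearn.pipeline import Pipeline

from gcfkit.families import (
    GCFClusterer,
    call_families,
    edges_to_score_matrix,
    network_edges,
    to_distance,
    upgma,
)
from gcfkit.similarity import BGCSimilarity, similarity_matrix

from _oracles import threshold_components


def random_distance_matrix(n, rng):
    d = rng.random((n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


class TestToDistance:
    @pytest.mark.parametrize(
        ("score", "dist"), [(0.45, 0.55), (1.0, 0.0), (0.0, 1.0)]
    )
    def test_known_correspondences(self, score, dist):
        assert to_distance(score) == pytest.approx(dist)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            to_distance(1.2)


class TestCallFamilies:
    def test_pair_plus_singleton(self):
        d = np.array([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]])
        a = call_families(d, ids=["c1", "c2", "c3"])
        assert a.assignments["c1"] == a.assignments["c2"] == 0
        assert a.assignments["c3"] is None
        assert a.n_families == 1

    def test_density_chaining_joins_a_chain(self):
        d = np.array([[0, 0.5, 0.9], [0.5, 0, 0.5], [0.9, 0.5, 0]])
        a = call_families(d)
        labs = set(a.assignments.values())
        assert labs == {0}

    def test_all_far_apart_means_all_singletons(self):
        d = random_distance_matrix(4, np.random.default_rng(1))
        d[d > 0] = 0.9
        a = call_families(d)
        assert a.n_families == 0
        assert len(a.singletons) == 4

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 0.2], [0.4, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            call_families(d)

    def test_equals_connected_components_exhaustively(self, rng):
        """DBSCAN with min_members=2 equals epsilon-threshold components."""
        for n in range(2, 8):
            for _ in range(30):
                d = random_distance_matrix(n, rng)
                a = call_families(d, epsilon=0.55)
                got = a.to_labels([str(i) for i in range(n)])
                want = threshold_components(d, 0.55)
                assert adjusted_rand_score(got, want) == pytest.approx(1.0)

    def test_raising_epsilon_never_shrinks_families(self, rng):
        for _ in range(10):
            d = random_distance_matrix(6, rng)
            small = call_families(d, epsilon=0.3)
            large = call_families(d, epsilon=0.7)
            # every family at the smaller epsilon stays together at the larger
            ids = [str(i) for i in range(6)]
            lab_small = dict(zip(ids, small.to_labels(ids)))
            lab_large = dict(zip(ids, large.to_labels(ids)))
            for fam in small.families().values():
                assert len({lab_large[c] for c in fam}) == 1
            assert len(large.singletons) <= len(small.singletons)


class TestNetworkEdges:
    def test_threshold_is_inclusive(self, toy_clusters):
        res = similarity_matrix(toy_clusters)
        # fabricate scores around the boundary
        res.edges = [
            type(res.edges[0])(f"a{i}", f"b{i}", s, 0.0, s, 0)
            for i, s in enumerate([0.46, 0.45, 0.44])
        ]
        assert len(network_edges(res, 0.45)) == 2

    def test_components_match_called_families(self, two_family_sim):
        _, clusters, _ = two_family_sim
        res = similarity_matrix(clusters)
        edges = network_edges(res, 0.45)
        a = call_families(res.distance(), epsilon=0.55)
        # vertices joined by network edges share a family, and vice versa
        for u, v, _ in edges:
            assert a.assignments[u] == a.assignments[v]
        n_connected = {u for u, v, _ in edges} | {v for u, v, _ in edges}
        assert n_connected == {
            cid for cid, lab in a.assignments.items() if lab is not None
        }


class TestUPGMA:
    def test_hand_worked_three_leaf_example(self, upgma_hand_matrix):
        tree = upgma(upgma_hand_matrix)
        assert tree.to_newick() == "((A:0.1,B:0.1):0.25,C:0.35);"
        assert tree.height == pytest.approx(0.35)
        inner = tree.children[0]
        assert inner.height == pytest.approx(0.1)

    def test_two_leaves_merge_at_half_distance(self):
        d = pd.DataFrame([[0, 0.4], [0.4, 0]], index=["X", "Y"], columns=["X", "Y"])
        tree = upgma(d)
        assert tree.height == pytest.approx(0.2)
        assert sorted(tree.leaves()) == ["X", "Y"]

    def test_heights_non_decreasing_to_root(self, rng):
        for _ in range(10):
            d = random_distance_matrix(5, rng)
            tree = upgma(d)

            def check(node):
                for c in node.children:
                    assert c.height <= node.height + 1e-12
                    check(c)

            check(tree)

    def test_root_height_matches_scipy_average_linkage(self, rng):
        d = random_distance_matrix(6, rng)
        tree = upgma(d)
        Z = linkage(squareform(d), method="average")
        assert tree.height == pytest.approx(Z[-1, 2] / 2)

    def test_reconstructs_ultrametric_topology(self):
        # generating tree: ((A,B) at h=0.1, C at h=0.3) vs (D,E) at h=0.2,
        # root at h=0.45 -> distances are twice the lowest common height
        heights = {
            frozenset("AB"): 0.1,
            frozenset("AC"): 0.3,
            frozenset("BC"): 0.3,
            frozenset("DE"): 0.2,
        }
        ids = list("ABCDE")
        d = np.zeros((5, 5))
        for i, x in enumerate(ids):
            for j, y in enumerate(ids):
                if i != j:
                    h = heights.get(frozenset(x + y), 0.45)
                    d[i, j] = 2 * h
        tree = upgma(pd.DataFrame(d, index=ids, columns=ids))
        assert tree.height == pytest.approx(0.45)
        left, right = tree.children
        assert sorted(left.leaves()) == ["A", "B", "C"]
        assert sorted(right.leaves()) == ["D", "E"]
        assert sorted(left.children[0].leaves()) == ["A", "B"]

    def test_nan_rejected(self):
        d = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(ValueError, match="NaN"):
            upgma(d)


class TestGCFClustererEstimator:
    def test_labels_are_contiguous_with_noise(self):
        d = np.array(
            [
                [0, 0.1, 0.9, 0.9],
                [0.1, 0, 0.9, 0.9],
                [0.9, 0.9, 0, 0.2],
                [0.9, 0.9, 0.2, 0],
            ]
        )
        est = GCFClusterer().fit(d)
        assert sorted(set(est.labels_)) == [0, 1]

    def test_similarity_input_mode_matches_distance_mode(self, rng):
        d = random_distance_matrix(5, rng)
        a = GCFClusterer(input="distance").fit(d).labels_
        b = GCFClusterer(input="similarity").fit(1 - d).labels_
        assert (a == b).all()

    def test_sklearn_pipeline_composition(self, two_family_sim):
        _, clusters, truth = two_family_sim
        pipe = Pipeline(
            [
                ("similarity", BGCSimilarity()),
                ("gcf", GCFClusterer(input="similarity")),
            ]
        )
        labels = pipe.fit_predict(clusters)
        ids = [c.cluster_id for c in clusters]
        # noise points get unique labels for partition comparison
        labels = [
            lab if lab != -1 else 100 + i for i, lab in enumerate(labels)
        ]
        assert adjusted_rand_score(labels, truth.to_labels(ids)) == pytest.approx(1.0)


def test_edges_to_score_matrix_roundtrip(two_family_sim):
    _, clusters, _ = two_family_sim
    res = similarity_matrix(clusters)
    mat = edges_to_score_matrix(res.edges)
    ids = sorted(res.ids)
    assert np.allclose(mat.loc[ids, ids].values, res.score.loc[ids, ids].values)
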