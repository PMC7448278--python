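"""Alignment, identity, Jaccard and combined-score behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcfkit.records import ClusterRecord
from gcfkit.similarity import (
    BGCSimilarity,
    GappedAlignment,
    ScoreWeights,
    backbone_identity,
    combined_score,
    global_align,
    greedy_match,
    jaccard_similarity,
    percent_identity,
    similarity_matrix,
)

from _oracles import best_matching_median, gotoh_score


class TestGlobalAlign:
    def test_identical_sequences_align_without_gaps(self):
        aln = global_align("ACDEFG", "ACDEFG")
        assert aln.a == aln.b == "ACDEFG"
        assert percent_identity(aln) == 1.0

    def test_single_mismatch_column(self):
        aln = global_align("ACDEFG", "ACDEYG")
        assert "-" not in aln.a + aln.b
        assert percent_identity(aln) == pytest.approx(5 / 6)

    def test_length_mismatch_introduces_gaps(self):
        aln = global_align("ACD", "A")
        assert aln.b.count("-") == 2
        assert len(aln.a) == len(aln.b) == 3

    def test_degapping_recovers_inputs(self):
        aln = global_align("MKTWLAEQ", "MKWLA")
        assert aln.a.replace("-", "") == "MKTWLAEQ"
        assert aln.b.replace("-", "") == "MKWLA"

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACD")

    def test_scores_match_affine_gap_dp_oracle(self, rng):
        """Alignment scores equal an independent Gotoh DP on short pairs."""
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(60):
            la, lb = rng.integers(1, 9, size=2)
            a = "".join(rng.choice(aa, size=la))
            b = "".join(rng.choice(aa, size=lb))
            aln = global_align(a, b)
            assert aln.score == pytest.approx(gotoh_score(a, b)), (a, b)


class TestPercentIdentity:
    def test_all_gap_row_scores_zero(self):
        aln = GappedAlignment(a="---", b="ACD", score=0.0)
        assert percent_identity(aln) == 0.0

    def test_zero_length_alignment_rejected(self):
        with pytest.raises(ValueError):
            percent_identity(GappedAlignment(a="", b="", score=0.0))


class TestJaccard:
    @pytest.mark.parametrize(
        ("a", "b", "expected"),
        [
            ({"KS", "AT"}, {"KS", "C"}, 1 / 3),
            ({"KS", "AT"}, {"KS", "AT"}, 1.0),
            ({"KS"}, {"C"}, 0.0),
            (set(), set(), 0.0),
        ],
    )
    def test_known_values(self, a, b, expected):
        assert jaccard_similarity(a, b) == pytest.approx(expected)


class TestCombinedScore:
    def test_printed_coefficients(self):
        assert combined_score(1.0, 0.0) == pytest.approx(0.8)
        assert combined_score(0.0, 1.0) == pytest.approx(0.2)
        assert combined_score(0.75, 0.5) == pytest.approx(0.7)

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError):
            ScoreWeights(0.8, 0.3)

    @settings(derandomize=True, max_examples=60)
    @given(
        id1=st.floats(0, 1),
        id2=st.floats(0, 1),
        jac=st.floats(0, 1),
    )
    def test_monotone_in_identity_at_fixed_jaccard(self, id1, id2, jac):
        lo, hi = sorted((id1, id2))
        assert combined_score(lo, jac) <= combined_score(hi, jac) + 1e-12

    @settings(derandomize=True, max_examples=60)
    @given(ident=st.floats(0, 1), j1=st.floats(0, 1), j2=st.floats(0, 1))
    def test_monotone_in_jaccard_at_fixed_identity(self, ident, j1, j2):
        lo, hi = sorted((j1, j2))
        assert combined_score(ident, lo) <= combined_score(ident, hi) + 1e-12


class TestBackboneIdentity:
    def test_identical_single_domain(self, toy_clusters):
        c = toy_clusters[0]
        ident, n = backbone_identity(c, c)
        assert (ident, n) == (1.0, 2)

    def test_no_shared_types(self, toy_clusters):
        assert backbone_identity(toy_clusters[0], toy_clusters[2]) == (0.0, 0)

    def test_greedy_matching_agrees_with_exhaustive_on_2x2(self):
        idm = np.array([[0.9, 0.2], [0.3, 0.8]])
        matched = greedy_match(idm)
        vals = sorted(v for _, _, v in matched)
        assert vals == [0.8, 0.9]
        assert np.median(vals) == pytest.approx(best_matching_median(idm))

    def test_greedy_matching_is_maximal_and_one_to_one(self, rng):
        for _ in range(25):
            r, c = rng.integers(1, 5, size=2)
            idm = rng.random((r, c))
            matched = greedy_match(idm)
            assert len(matched) == min(r, c)
            rows = [i for i, _, _ in matched]
            cols = [j for _, j, _ in matched]
            assert len(set(rows)) == len(rows) and len(set(cols)) == len(cols)
            i0, j0, v0 = matched[0]
            assert v0 == idm.max()


class TestSimilarityMatrix:
    def test_identical_clusters_score_one(self, toy_clusters):
        a = toy_clusters[0]
        b = ClusterRecord(
            cluster_id="copy",
            genome_id=a.genome_id,
            product_class=a.product_class,
            domain_array=list(a.domain_array),
            backbone_domains={k: list(v) for k, v in a.backbone_domains.items()},
        )
        res = similarity_matrix([a, b])
        assert res.score.loc["bgc1", "copy"] == pytest.approx(1.0)

    def test_matrix_matches_per_pair_scores_and_is_symmetric(self, toy_clusters):
        res = similarity_matrix(toy_clusters)
        assert np.allclose(res.score.values, res.score.values.T)
        assert np.allclose(np.diag(res.score.values), 1.0)
        for e in res.edges:
            expected = combined_score(e.seq_identity, e.jaccard)
            assert e.score == pytest.approx(expected)
            assert res.score.loc[e.cluster_a, e.cluster_b] == pytest.approx(e.score)

    def test_edge_count_is_n_choose_2(self, two_family_sim):
        _, clusters, _ = two_family_sim
        res = similarity_matrix(clusters)
        n = len(clusters)
        assert len(res.edges) == n * (n - 1) // 2

    def test_duplicate_ids_rejected(self, toy_clusters):
        with pytest.raises(ValueError, match="duplicate"):
            similarity_matrix([toy_clusters[0], toy_clusters[0]])


class TestBGCSimilarityEstimator:
    def test_fit_transform_returns_square_score_matrix(self, toy_clusters):
        est = BGCSimilarity()
        mat = est.fit_transform(toy_clusters)
        assert mat.shape == (3, 3)
        assert np.allclose(np.diag(mat), 1.0)
        ref = similarity_matrix(toy_clusters).score.to_numpy()
        assert np.allclose(mat, ref)

    def test_get_params_roundtrip(self):
        est = BGCSimilarity(w_id=0.7, w_jac=0.3)
        clone = BGCSimilarity(**{
            k: v for k, v in est.get_params().items()
        })
        assert clone.w_id == 0.7 and clone.w_jac == 0.3

    def test_transform_against_fitted_reference(self, toy_clusters):
        est = BGCSimilarity().fit(toy_clusters[:2])
        cross = est.transform([toy_clusters[2]])
        assert cross.shape == (1, 2)
        assert (cross <= 1).all() and (cross >= 0).all()
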