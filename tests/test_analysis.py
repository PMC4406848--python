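"""Event detection, ROC evaluation, dissimilarities, and clustering."""

import io

import numpy as np
import pytest
from Bio import Phylo

from rprpca import (
    Decomposition,
    DissimilarityMatrix,
    correlation_score,
    dendrogram_newick,
    detect_onsets,
    dissimilarity_disentangled,
    dissimilarity_raw,
    extract_template,
    hierarchical_cluster,
    roc_auc,
    roc_curve,
)


class TestExtractTemplate:
    def test_rank_one_returns_right_vector(self, rng):
        v = rng.standard_normal(12)
        L = np.outer(np.abs(rng.standard_normal(6)) + 0.5, v)
        tpl = extract_template(L)
        c = np.corrcoef(tpl, v)[0, 1]
        assert abs(c) > 1 - 1e-10

    def test_sign_convention(self, rng):
        L = np.outer(np.ones(4), [-3.0, 1.0, 0.5])
        tpl = extract_template(L)
        assert tpl[np.argmax(np.abs(tpl))] > 0

    def test_row_mean_method(self):
        L = np.tile([1.0, 2.0, 3.0], (5, 1))
        np.testing.assert_allclose(extract_template(L, method="mean"),
                                   [1.0, 2.0, 3.0])

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            extract_template(np.zeros((3, 3)))


class TestCorrelationScore:
    def test_exact_match_scores_one(self, rng):
        tpl = rng.standard_normal(12)
        stream = np.concatenate([rng.standard_normal(10), tpl.reshape(4, 3)[0],
                                 ]).reshape(1, -1)
        # simpler: single species stream containing the template verbatim
        tpl1 = rng.standard_normal(6)
        stream = np.concatenate([rng.standard_normal(5), tpl1,
                                 rng.standard_normal(5)])[None, :]
        scores = correlation_score(stream, tpl1)
        assert scores[5] == pytest.approx(1.0)

    def test_negated_match_scores_minus_one(self, rng):
        tpl = rng.standard_normal(6)
        stream = (-tpl)[None, :]
        assert correlation_score(stream, tpl)[0] == pytest.approx(-1.0)

    def test_noise_scores_near_zero(self):
        rng = np.random.default_rng(0)
        tpl = rng.standard_normal(10)
        stream = rng.standard_normal((1, 200))
        scores = correlation_score(stream, tpl)
        assert len(scores) >= 100
        assert abs(scores.mean()) < 0.1

    def test_species_major_windows(self, rng):
        # template laid out species-major must match a 2-species stream
        footprint = rng.standard_normal((2, 5))
        tpl = footprint.ravel()
        stream = np.hstack([rng.standard_normal((2, 7)), footprint,
                            rng.standard_normal((2, 4))])
        scores = correlation_score(stream, tpl)
        assert np.argmax(scores) == 7
        assert scores[7] == pytest.approx(1.0)

    def test_zero_variance_window_scores_zero(self, caplog):
        tpl = np.array([1.0, -1.0, 0.5])
        stream = np.zeros((1, 5))
        with caplog.at_level("INFO", logger="rprpca"):
            scores = correlation_score(stream, tpl)
        np.testing.assert_array_equal(scores, 0.0)


class TestDetectionAndRoc:
    def test_rising_edges_only(self):
        scores = np.array([0.0, 0.8, 0.9, 0.2, 0.85, 0.9, 0.9, 0.1])
        res = detect_onsets(scores, threshold=0.7)
        np.testing.assert_array_equal(res.detected_onsets, [1, 4])

    def test_threshold_above_max_gives_origin(self):
        scores = np.linspace(-1, 1, 50)
        curve = roc_curve(scores, [25], thresholds=[1.5])
        assert tuple(curve[0, 1:]) == (0.0, 0.0)

    def test_threshold_below_min_gives_full_tpr(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(-0.5, 0.5, 100)
        curve = roc_curve(scores, [10, 50, 90], thresholds=[-2.0])
        assert curve[0, 2] == 1.0

    def test_requires_onsets(self):
        with pytest.raises(ValueError):
            roc_curve(np.zeros(10), [])

    def test_embedded_templates_detected(self):
        # 20 bumps at SNR 2: detection must be near-perfect
        rng = np.random.default_rng(3)
        tpl = np.exp(-0.5 * ((np.arange(10) - 5) / 2.0) ** 2)
        stream = rng.standard_normal(1200) * np.sqrt(np.mean(tpl**2)) / 2.0
        onsets = np.arange(20) * 55 + 10
        for t in onsets:
            stream[t:t + 10] += tpl
        scores = correlation_score(stream[None, :], tpl)
        curve = roc_curve(scores, onsets, match_window=5)
        assert roc_auc(curve) > 0.9

    def test_auc_of_perfect_separation(self):
        scores = np.zeros(100)
        scores[[20, 60]] = 1.0
        curve = roc_curve(scores, [20, 60], match_window=2)
        assert roc_auc(curve) == pytest.approx(1.0)


class TestDissimilarities:
    def test_self_distance_zero(self, rng):
        X = rng.standard_normal((5, 8))
        D = dissimilarity_raw(X)
        np.testing.assert_allclose(np.diag(D.d), 0.0, atol=1e-12)

    def test_anticorrelated_rows_distance_two(self, rng):
        x = rng.standard_normal(10)
        D = dissimilarity_raw(np.vstack([x, -x]))
        assert D.d[0, 1] == pytest.approx(2.0)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(10)
        D = dissimilarity_raw(np.vstack([x, 3.0 * x + 7.0]))
        assert D.d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_bounds_symmetry(self, rng):
        X = rng.standard_normal((10, 6))
        D = dissimilarity_raw(X).d
        assert np.all(D >= 0) and np.all(D <= 2 + 1e-12)
        np.testing.assert_allclose(D, D.T)

    def test_gamma_zero_is_raw_distance_on_L(self, rng):
        L = rng.standard_normal((6, 10))
        S = rng.standard_normal((6, 10))
        dec = Decomposition(L, S, lam=0.3)
        a = dissimilarity_disentangled(dec, gamma=0.0).d
        b = dissimilarity_raw(L).d
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_all_zero_sparse_part_reduces_to_L(self, rng):
        L = rng.standard_normal((6, 10))
        dec = Decomposition(L, np.zeros_like(L), lam=0.3)
        for gamma in (0.25, 0.5, 1.0):
            got = dissimilarity_disentangled(dec, gamma=gamma).d
            # both-zero sparse rows contribute 0, so only the L term scales
            np.testing.assert_allclose(got,
                                       (1 - gamma) * dissimilarity_raw(L).d,
                                       atol=1e-12)

    def test_zero_vs_nonzero_sparse_row_max_distance(self, rng):
        L = np.tile(rng.standard_normal(10), (2, 1))
        S = np.vstack([np.zeros(10), rng.standard_normal(10)])
        d = dissimilarity_disentangled(Decomposition(L, S, lam=0.1),
                                       gamma=1.0).d
        assert d[0, 1] == pytest.approx(1.0)

    def test_identical_rows_zero_distance(self, rng):
        L = np.tile(rng.standard_normal(10), (3, 1))
        S = np.tile(rng.standard_normal(10), (3, 1))
        d = dissimilarity_disentangled(Decomposition(L, S, lam=0.1)).d
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_invalid_gamma_rejected(self, rng):
        dec = Decomposition(np.eye(3), np.eye(3), lam=0.1)
        with pytest.raises(ValueError):
            dissimilarity_disentangled(dec, gamma=1.5)


class TestClustering:
    def test_single_row(self):
        D = DissimilarityMatrix(np.zeros((1, 1)))
        np.testing.assert_array_equal(hierarchical_cluster(D, 1), [0])

    def test_perfect_two_group_split(self):
        d = np.full((6, 6), 2.0)
        d[:3, :3] = 0.0
        d[3:, 3:] = 0.0
        np.fill_diagonal(d, 0.0)
        labels = hierarchical_cluster(DissimilarityMatrix(d), 2)
        assert len(set(labels[:3])) == 1
        assert len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_permutation_invariant_up_to_relabel(self, rng):
        d = np.abs(rng.standard_normal((8, 8)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        perm = rng.permutation(8)
        base = hierarchical_cluster(DissimilarityMatrix(d), 3)
        permd = hierarchical_cluster(DissimilarityMatrix(d[perm][:, perm]), 3)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(base[perm], permd) == pytest.approx(1.0)

    def test_k_validated(self):
        D = DissimilarityMatrix(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            hierarchical_cluster(D, 5)

    def test_newick_export_is_parseable(self, rng):
        d = np.abs(rng.standard_normal((5, 5)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        D = DissimilarityMatrix(d, row_labels=[f"exp{i}" for i in range(5)])
        tree = Phylo.read(io.StringIO(dendrogram_newick(D)), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == [
            f"exp{i}" for i in range(5)]
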