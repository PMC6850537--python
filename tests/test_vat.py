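"""VAT reordering, the iVAT minimax transform, back-pass and image export."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

import spikevat as sv
from conftest import brute_force_minimax, random_dissimilarity


class TestPairwiseEuclidean:
    def test_three_four_five_triangle(self):
        d = sv.pairwise_euclidean(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert d.values[0, 1] == pytest.approx(5.0)

    def test_single_object(self):
        d = sv.pairwise_euclidean(np.array([[1.0, 2.0]]))
        np.testing.assert_array_equal(d.values, np.zeros((1, 1)))

    def test_matches_double_loop(self, rng):
        x = rng.normal(size=(10, 5))
        d = sv.pairwise_euclidean(x).values
        for i in range(10):
            for j in range(10):
                assert d[i, j] == pytest.approx(
                    np.linalg.norm(x[i] - x[j]), abs=1e-12
                )

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            sv.pairwise_euclidean(np.array([[np.nan, 0.0]]))


class TestDissimilarityMatrix:
    @pytest.mark.parametrize(
        "bad",
        [
            np.array([[0.0, 1.0], [2.0, 0.0]]),   # asymmetric
            np.array([[1.0, 1.0], [1.0, 0.0]]),   # nonzero diagonal
            np.array([[0.0, -1.0], [-1.0, 0.0]]),  # negative entry
        ],
    )
    def test_invalid_matrices_rejected(self, bad):
        with pytest.raises(ValueError):
            sv.DissimilarityMatrix(bad)

    def test_non_metric_matrix_accepted(self):
        """Triangle-inequality violations are admissible."""
        d = np.array([[0.0, 1.0, 100.0], [1.0, 0.0, 1.0], [100.0, 1.0, 0.0]])
        assert sv.vat_reorder(d).order.size == 3


class TestVatReorder:
    def test_gapped_line_hand_example(self, gapped_line):
        """{0, 0.1, 5, 5.1}: start at the far endpoint pair's smaller index;
        insertion order walks each tight pair; superdiagonal 0.1, 4.9, 0.1."""
        r = sv.vat_reorder(sv.pairwise_euclidean(gapped_line))
        np.testing.assert_array_equal(r.order, [0, 1, 2, 3])
        np.testing.assert_allclose(np.diag(r.d_star, 1), [0.1, 4.9, 0.1])
        assert len(r.mst_edges) == 3

    def test_two_objects(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        r = sv.vat_reorder(d)
        assert sorted(r.order.tolist()) == [0, 1]
        np.testing.assert_array_equal(r.d_star, d)

    def test_order_is_permutation_and_dstar_is_conjugation(self, rng):
        d = random_dissimilarity(rng, 15)
        r = sv.vat_reorder(d)
        assert sorted(r.order.tolist()) == list(range(15))
        np.testing.assert_allclose(r.d_star, d[np.ix_(r.order, r.order)])
        # the MST spans all objects
        touched = {v for e in r.mst_edges for v in e[:2]}
        assert touched == set(range(15))

    def test_start_is_endpoint_of_longest_edge(self, rng):
        for _ in range(20):
            d = random_dissimilarity(rng, 12)
            r = sv.vat_reorder(d)
            i, j = np.unravel_index(np.argmax(d), d.shape)
            assert r.order[0] in (i, j)

    def test_shuffle_invariance_of_reordered_matrix(self, rng):
        """Permuting object order changes nothing structural: sorted rows of
        D* (and its spectrum) match across 20 shuffles."""
        d = random_dissimilarity(rng, 10)
        base = sv.vat_reorder(d).d_star
        base_rows = np.sort(np.sort(base, axis=1), axis=0)
        base_spec = np.sort(np.linalg.eigvalsh(base))
        for _ in range(20):
            perm = rng.permutation(10)
            shuffled = d[np.ix_(perm, perm)]
            ds = sv.vat_reorder(shuffled).d_star
            np.testing.assert_allclose(
                np.sort(np.sort(ds, axis=1), axis=0), base_rows, atol=1e-9
            )
            np.testing.assert_allclose(
                np.sort(np.linalg.eigvalsh(ds)), base_spec, atol=1e-9
            )

    def test_single_object_rejected(self):
        with pytest.raises(ValueError):
            sv.vat_reorder(np.zeros((1, 1)))


class TestIvatTransform:
    def test_gapped_line_minimax_values(self, gapped_line):
        """Within-pair entries stay 0.1; every crossing path is dominated by
        the single 4.9 gap edge."""
        r = sv.ivat(sv.pairwise_euclidean(gapped_line))
        dp = r.d_prime_star
        expected = np.array(
            [
                [0.0, 0.1, 4.9, 4.9],
                [0.1, 0.0, 4.9, 4.9],
                [4.9, 4.9, 0.0, 0.1],
                [4.9, 4.9, 0.1, 0.0],
            ]
        )
        np.testing.assert_allclose(dp, expected)

    def test_two_objects_identity(self):
        d = np.array([[0.0, 3.0], [3.0, 0.0]])
        r = sv.ivat(d)
        np.testing.assert_array_equal(r.d_prime_star, r.d_star)

    def test_equals_full_graph_minimax_oracle(self, rng):
        for _ in range(100):
            d = random_dissimilarity(rng, 12)
            r = sv.ivat(d)
            oracle = brute_force_minimax(d)[np.ix_(r.order, r.order)]
            np.testing.assert_allclose(r.d_prime_star, oracle, atol=1e-9)

    def test_bounded_by_max_entry(self, rng):
        d = random_dissimilarity(rng, 15)
        r = sv.ivat(d)
        assert r.d_prime_star.max() <= d.max() + 1e-12
        assert np.allclose(r.d_prime_star, r.d_prime_star.T)
        assert np.all(np.diag(r.d_prime_star) == 0)

    def test_missing_mst_rejected(self):
        bare = sv.VatResult(order=np.array([0]), mst_edges=(), d_star=np.zeros((1, 1)))
        with pytest.raises(ValueError):
            sv.ivat_transform(bare)


class TestSingleLinkageBackPass:
    def test_gapped_line_cut(self, gapped_line):
        r = sv.vat_reorder(sv.pairwise_euclidean(gapped_line))
        part = sv.single_linkage_partition(r, 2)
        np.testing.assert_array_equal(part.labels, [1, 1, 2, 2])

    def test_extreme_k(self, gapped_line):
        r = sv.vat_reorder(sv.pairwise_euclidean(gapped_line))
        assert sv.single_linkage_partition(r, 1).k == 1
        assert sv.single_linkage_partition(r, 4).k == 4
        with pytest.raises(ValueError):
            sv.single_linkage_partition(r, 5)

    def test_agrees_with_agglomerative_single_linkage(self, rng):
        """The back pass reproduces scipy's single-linkage flat clusters for
        every k on random instances."""
        from sklearn.metrics import adjusted_rand_score

        for _ in range(25):
            n = int(rng.integers(5, 20))
            x = rng.normal(size=(n, 3))
            d = sv.pairwise_euclidean(x)
            r = sv.vat_reorder(d)
            z = linkage(squareform(d.values, checks=False), method="single")
            for k in range(1, n + 1):
                ours = sv.single_linkage_partition(r, k).labels
                ref = fcluster(z, t=k, criterion="maxclust")
                # same partition up to relabeling
                assert adjusted_rand_score(ours, ref) == pytest.approx(1.0)


class TestClusterCountEstimate:
    def test_gapped_line_suggests_two(self, gapped_line):
        r = sv.vat_reorder(sv.pairwise_euclidean(gapped_line))
        assert sv.estimate_cluster_count(r, 10) == 2

    def test_equal_edges_suggest_one(self):
        # 4 equally spaced collinear points: all MST edges equal
        x = np.arange(4.0)[:, None]
        r = sv.vat_reorder(sv.pairwise_euclidean(x))
        assert sv.estimate_cluster_count(r, 10) == 1

    def test_three_separated_groups(self, rng):
        centers = np.array([0.0, 50.0, 100.0])
        pts = np.concatenate([c + rng.uniform(0, 1, size=5) for c in centers])
        r = sv.vat_reorder(sv.pairwise_euclidean(pts[:, None]))
        assert sv.estimate_cluster_count(r, 10) == 3

    def test_cap_applies(self, gapped_line):
        r = sv.vat_reorder(sv.pairwise_euclidean(gapped_line))
        assert sv.estimate_cluster_count(r, 1) == 1


class TestImageExport:
    def test_zero_matrix_renders_black(self, tmp_path):
        out = tmp_path / "zero.png"
        pixels = sv.render_ivat_image(np.zeros((2, 2)), out)
        assert out.exists()
        assert pixels.dtype == np.uint8
        np.testing.assert_array_equal(pixels, 0)

    def test_gapped_line_block_structure(self, gapped_line, tmp_path):
        """Two dark 2x2 diagonal blocks; the max entry maps to 255."""
        import imageio.v3 as iio

        r = sv.ivat(sv.pairwise_euclidean(gapped_line))
        out = tmp_path / "ivat.png"
        sv.render_ivat_image(r.d_prime_star, out)
        img = iio.imread(out)
        assert img.shape == (4, 4)
        expected = np.round(255 * r.d_prime_star / r.d_prime_star.max())
        np.testing.assert_array_equal(img, expected.astype(np.uint8))
        assert img[0, 1] == round(255 * 0.1 / 4.9)  # dark within-block pixel
        assert img[0, 2] == 255  # bright cross-block pixel

    def test_runtime_scales_quadratically(self):
        """Doubling n roughly quadruples VAT+iVAT wall time (loose bound)."""
        import time

        rng = np.random.default_rng(0)

        def timed(n):
            d = sv.pairwise_euclidean(rng.normal(size=(n, 3))).values
            t0 = time.perf_counter()
            sv.ivat(d)
            return time.perf_counter() - t0

        timed(200)  # warm-up
        t1 = min(timed(500) for _ in range(3))
        t2 = min(timed(1000) for _ in range(3))
        assert t2 / t1 < 16  # far below cubic growth; informational bound
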