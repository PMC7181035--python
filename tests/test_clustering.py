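import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from urbanhealth.clustering import (
    kmeans_grid_search,
    rotation_invariance_check,
    tsne_diagnostic,
)
from urbanhealth.embedding import ExtractorSpec, baseline_extractor
from urbanhealth.synthetic import default_archetypes, generate_tile_texture


def gaussian_blobs(n_blobs, n_per, dim=10, sep=20.0, seed=0):
    """Well-separated spherical blobs: centers sep*sigma apart, sigma = 1."""
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, 1, (n_blobs, dim))
    centers = centers / np.linalg.norm(centers, axis=1, keepdims=True) * sep
    x = np.vstack([rng.normal(c, 1.0, (n_per, dim)) for c in centers])
    truth = np.repeat(np.arange(1, n_blobs + 1), n_per)
    return x, truth


class TestKmeansGridSearch:
    @pytest.mark.parametrize("k_true", [2, 4])
    def test_recovers_planted_k(self, k_true):
        x, truth = gaussian_blobs(k_true, 50, seed=0)
        res = kmeans_grid_search(x, k_min=2, k_max=6, n_reruns=10, seed=0)
        assert res.chosen_k == k_true
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_deterministic_given_seed(self):
        x, _ = gaussian_blobs(3, 30, seed=1)
        r1 = kmeans_grid_search(x, seed=7)
        r2 = kmeans_grid_search(x, seed=7)
        assert np.array_equal(r1.labels, r2.labels)
        assert r1.silhouette_by_k.equals(r2.silhouette_by_k)

    def test_row_permutation_equivariance(self):
        x, _ = gaussian_blobs(3, 30, seed=2)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(x))
        r = kmeans_grid_search(x, seed=0)
        rp = kmeans_grid_search(x[perm], seed=0)
        # identical partition up to label permutation
        assert adjusted_rand_score(r.labels[perm], rp.labels) == 1.0

    def test_silhouette_bounds_and_inertia_monotone(self):
        x, _ = gaussian_blobs(4, 40, seed=3)
        res = kmeans_grid_search(x, seed=0)
        sil = res.silhouette_by_k["silhouette"]
        assert ((sil >= -1) & (sil <= 1)).all()
        inertia = res.silhouette_by_k["inertia"].to_numpy()
        assert (np.diff(inertia) <= 1e-9).all()

    def test_duplicated_rows_share_labels(self):
        x, _ = gaussian_blobs(3, 20, seed=4)
        xx = np.vstack([x, x[:5]])
        res = kmeans_grid_search(xx, seed=0)
        assert np.array_equal(res.labels[len(x):], res.labels[:5])

    def test_labels_cover_one_to_k(self):
        x, _ = gaussian_blobs(4, 30, seed=5)
        res = kmeans_grid_search(x, seed=0)
        assert set(res.labels) == set(range(1, res.chosen_k + 1))

    def test_greenness_orders_cluster_ids(self):
        x, truth = gaussian_blobs(3, 30, seed=6)
        green = np.where(truth == 2, 1.0, np.where(truth == 1, 0.5, 0.0))
        res = kmeans_grid_search(x, seed=0, greenness_scores=green)
        by_cluster = [green[res.labels == c].mean() for c in range(1, res.chosen_k + 1)]
        assert by_cluster == sorted(by_cluster, reverse=True)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            kmeans_grid_search(np.zeros((50, 3)), seed=0)  # identical rows
        with pytest.raises(ValueError):
            kmeans_grid_search(np.random.default_rng(0).random((5, 3)), k_max=6)


class TestTsneDiagnostic:
    def test_shape_and_determinism(self):
        x, truth = gaussian_blobs(2, 20, seed=0)
        m1 = tsne_diagnostic(x, truth, seed=3)
        m2 = tsne_diagnostic(x, truth, seed=3)
        assert m1.coordinates.shape == (len(x), 2)
        assert np.array_equal(m1.coordinates, m2.coordinates)
        assert np.array_equal(m1.labels, truth)
        assert np.all(np.isfinite(m1.coordinates))


class TestRotationInvarianceCheck:
    def _tiles(self, n=8, size=32):
        rng = np.random.default_rng(0)
        archs = default_archetypes()
        return [generate_tile_texture(archs[i % 4], rng, size=size) for i in range(n)]

    def test_invariant_extractor_pairs_everything(self):
        frac, tree = rotation_invariance_check(
            self._tiles(), baseline_extractor(), seed=0
        )
        assert frac == 1.0
        assert "children" in tree

    def test_single_pair(self):
        frac, _ = rotation_invariance_check(self._tiles(n=2), baseline_extractor(), seed=1)
        assert frac == 1.0

    def test_corner_extractor_can_fail_to_pair(self):
        # the raw top-left pixel moves under rotation
        corner = ExtractorSpec(
            "corner", 3, True, lambda px: np.asarray(px, float)[0, 0]
        )
        tiles = []
        rng = np.random.default_rng(2)
        for i in range(6):
            px = rng.integers(0, 255, (8, 8, 3)).astype(np.uint8)
            tiles.append(px)
        frac, _ = rotation_invariance_check(tiles, corner, seed=0)
        assert frac < 1.0

    def test_rejects_bad_angles(self):
        with pytest.raises(ValueError):
            rotation_invariance_check(self._tiles(), baseline_extractor(), angles=(45,))
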