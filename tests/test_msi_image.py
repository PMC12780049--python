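"""Rasterization, PCA colouring and tissue/background labelling."""

import numpy as np
import pytest

from spotfuse.errors import FormatError
from spotfuse.msi_image import (
    otsu_threshold,
    pca_rgb_image,
    pca_scores,
    rasterize,
    single_peak_image,
    tissue_labels_from_pc1,
)
from spotfuse.msi_io import MSIDataset


def make_ds(intensities, coords, mz=None):
    intensities = np.asarray(intensities, dtype=float)
    return MSIDataset(
        pixel_ids=np.arange(len(intensities)),
        coords=np.asarray(coords, dtype=float),
        mz=np.asarray(mz, float)
        if mz is not None
        else 100.0 + np.arange(intensities.shape[1]),
        intensities=intensities,
    ).validate()


def two_cluster_ds(seed=0, n=200):
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % 2 == 0
    base = np.where(labels[:, None], [100.0, 40.0, 10.0], [10.0, 5.0, 8.0])
    intens = np.abs(base + rng.normal(0, 1, size=(n, 3)))
    coords = np.column_stack([np.arange(n) % 20, np.arange(n) // 20])
    return make_ds(intens, coords), labels


class TestRasterize:
    def test_2x2_grid(self):
        ds = make_ds(
            np.arange(4.0)[:, None], coords=[(0, 0), (1, 0), (0, 1), (1, 1)]
        )
        img = rasterize(ds, ds.intensities[:, 0])
        assert img.shape == (2, 2)
        assert img.occupied.all()
        np.testing.assert_allclose(img.raster, [[0, 1], [2, 3]])

    def test_missing_pixel_flagged_fill(self):
        ds = make_ds(np.ones((3, 1)), coords=[(0, 0), (1, 0), (0, 1)])
        img = rasterize(ds, ds.intensities[:, 0])
        assert not img.occupied[1, 1]
        assert img.raster[1, 1] == 0

    def test_scaled_coords_infer_step(self):
        coords = 65.0 * np.array([(0, 0), (1, 0), (0, 1), (1, 1)])
        ds = make_ds(np.ones((4, 1)), coords=coords)
        img = rasterize(ds, ds.intensities[:, 0])
        assert img.shape == (2, 2)
        assert img.frame["x_step"] == 65.0
        assert img.frame["y_step"] == 65.0

    def test_inverse_frame_recovers_coords(self, msi):
        img = rasterize(msi, msi.intensities[:, 0])
        rc = img.native_to_raster(msi.coords)
        back = img.raster_to_native(np.round(rc))
        step = max(img.frame["x_step"], img.frame["y_step"])
        assert np.abs(back - msi.coords).max() < step / 2

    def test_collision_fatal(self):
        # off-grid x values 10 and 10.2 round into the same cell
        ds = make_ds(
            np.ones((4, 1)),
            coords=[(0.0, 0.0), (10.0, 0.0), (10.2, 0.0), (20.0, 0.0)],
        )
        with pytest.raises(FormatError, match="same raster cell"):
            rasterize(ds, ds.intensities[:, 0])


class TestPCA:
    def test_matches_eigendecomposition_oracle(self):
        ds, _ = two_cluster_ds()
        scores, loadings = pca_scores(ds, 2)
        X = ds.intensities - ds.intensities.mean(axis=0)
        # independent route: eigen-decomposition of the covariance matrix
        w, V = np.linalg.eigh(np.cov(X, rowvar=False))
        order = np.argsort(w)[::-1]
        V = V[:, order[:2]]
        for k in range(2):
            v = V[:, k]
            v = v * np.sign(v[np.argmax(np.abs(v))])
            np.testing.assert_allclose(loadings[:, k], v, atol=1e-8)
            np.testing.assert_allclose(scores[:, k], X @ v, atol=1e-6)

    def test_matches_sklearn(self):
        from sklearn.decomposition import PCA

        ds, _ = two_cluster_ds(seed=3)
        scores, _ = pca_scores(ds, 2)
        ref = PCA(n_components=2, svd_solver="full").fit_transform(ds.intensities)
        for k in range(2):
            s = scores[:, k]
            r = ref[:, k]
            agree = min(np.abs(s - r).max(), np.abs(s + r).max())
            assert agree < 1e-8

    def test_single_variance_direction_monotone(self):
        v = np.linspace(0, 50, 10)
        ds = make_ds(
            np.column_stack([v, np.full(10, 7.0)]),
            coords=np.column_stack([np.arange(10), np.zeros(10)]),
        )
        img = pca_rgb_image(ds, n_components=1)
        row = img.raster[0, :, 0]
        assert np.all(np.diff(row) >= 0) and row[-1] > row[0]

    def test_too_many_components_fatal(self):
        ds = make_ds(np.random.default_rng(0).uniform(1, 2, (5, 2)),
                     coords=np.column_stack([np.arange(5), np.zeros(5)]))
        with pytest.raises(FormatError, match="components"):
            pca_rgb_image(ds, n_components=3)

    def test_constant_data_fatal(self):
        ds = make_ds(np.full((4, 2), 3.0),
                     coords=np.column_stack([np.arange(4), np.zeros(4)]))
        with pytest.raises(FormatError, match="variance"):
            pca_rgb_image(ds, n_components=1)

    def test_invariant_to_pixel_order_and_peak_shift(self):
        ds, _ = two_cluster_ds(seed=5)
        img = pca_rgb_image(ds, n_components=2)
        perm = np.random.default_rng(1).permutation(ds.n_pixels)
        shifted = make_ds(ds.intensities[perm] + np.array([50.0, 0.0, 0.0]),
                          ds.coords[perm])
        img2 = pca_rgb_image(shifted, n_components=2)
        np.testing.assert_allclose(img.raster, img2.raster, atol=1e-6)


class TestSinglePeak:
    def test_uniform_intensity_uniform_raster(self):
        ds = make_ds(np.full((4, 1), 5.0), coords=[(0, 0), (1, 0), (0, 1), (1, 1)])
        img = single_peak_image(ds, 100.0)
        np.testing.assert_allclose(img.raster, 255.0)

    def test_hot_pixel_saturates_under_cap(self):
        vals = np.ones(200)
        vals[7] = 100.0
        coords = np.column_stack([np.arange(200) % 20, np.arange(200) // 20])
        ds = make_ds(vals[:, None], coords=coords)
        img = single_peak_image(ds, 100.0, cap_percentile=99)
        r, c = coords[7].astype(int)[::-1]
        assert img.raster[r, c] == 255.0
        assert np.percentile(img.raster[img.occupied], 50) > 200  # cap rescales rest

    def test_unknown_mz_lists_nearest(self):
        ds = make_ds(np.ones((2, 2)), coords=[(0, 0), (1, 0)], mz=[100.0, 200.0])
        with pytest.raises(FormatError, match="nearest is 200"):
            single_peak_image(ds, 199.0)

    def test_compound_peak_nonzero_only_in_hotspots(self, truth, msi):
        j = msi.peak_index(550.15724)
        v = msi.intensities[:, j]
        hot = truth.intensity_model[[p.mz for p in truth.intensity_model].index(550.15724)]
        centres = truth.warp.apply(msi.coords)
        in_hot = np.zeros(msi.n_pixels, dtype=bool)
        for cx, cy, r in hot.hotspots:
            in_hot |= (centres[:, 0] - cx) ** 2 + (centres[:, 1] - cy) ** 2 <= r**2
        assert v[~in_hot].max() == 0
        assert v[in_hot].mean() > 0


class TestTissueLabels:
    def test_otsu_equals_bruteforce_search(self):
        ds, _ = two_cluster_ds(seed=2)
        scores, _ = pca_scores(ds, 1)
        s = scores[:, 0]
        thr = otsu_threshold(s)
        # brute force over all 256 quantized candidate thresholds
        hist, edges = np.histogram(s, bins=256)
        best, best_t = -np.inf, None
        for k in range(1, 256):
            left = hist[:k].sum()
            right = hist[k:].sum()
            if left == 0 or right == 0:
                continue
            centers = (edges[:-1] + edges[1:]) / 2
            m1 = (hist[:k] * centers[:k]).sum() / left
            m2 = (hist[k:] * centers[k:]).sum() / right
            var = left * right * (m1 - m2) ** 2
            if var > best:
                best, best_t = var, edges[k]
        assert thr == pytest.approx(best_t, abs=1e-12)

    def test_orientation_by_total_intensity(self):
        ds, labels = two_cluster_ds(seed=4)
        out = tissue_labels_from_pc1(ds)
        # high-total cluster must be called tissue however PC1 is signed
        assert (out == labels).mean() > 0.99

    def test_explicit_threshold_matches_otsu_on_bimodal(self):
        ds, _ = two_cluster_ds(seed=6)
        scores, _ = pca_scores(ds, 1)
        auto = tissue_labels_from_pc1(ds, threshold="otsu")
        manual = tissue_labels_from_pc1(
            ds, threshold=float(np.mean([scores[:, 0].min(), scores[:, 0].max()]))
        )
        assert (auto == manual).mean() > 0.99

    def test_degenerate_threshold_warns(self):
        ds, _ = two_cluster_ds(seed=7)
        with pytest.warns(UserWarning, match="one class"):
            out = tissue_labels_from_pc1(ds, threshold=1e12)
        assert len(set(out)) == 1

    def test_ellipse_fixture_matches_generator_mask(self, msi):
        labels = tissue_labels_from_pc1(msi)
        truth_labels = (msi.pixel_meta["roi"] == "tissue").to_numpy()
        assert (labels == truth_labels).mean() >= 0.99
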