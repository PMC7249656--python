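import numpy as np
import pytest

from treatscan.features import (PredictorStack, ScenePair, compose_predictors,
                                fit_pca, focal_stats, pca_change, pca_scores,
                                prune_correlated, spectral_indices)
from conftest import make_raster


def brute_force_focal(values, stat):
    """Independent double-loop oracle for 3x3 focal statistics."""
    nr, nc = values.shape
    out = np.full((nr, nc), np.nan)
    for r in range(nr):
        for c in range(nc):
            if not np.isfinite(values[r, c]):
                continue
            window = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nr and 0 <= cc < nc and np.isfinite(values[rr, cc]):
                        window.append(values[rr, cc])
            w = np.array(window)
            out[r, c] = w.mean() if stat == "mean" else w.std()
    return out


class TestFitPCA:
    def test_orthonormal_loadings(self, rng):
        img = make_raster(rng.random((4, 10, 10)))
        m = fit_pca(img)
        np.testing.assert_allclose(m.loadings.T @ m.loadings, np.eye(4),
                                   atol=1e-10)

    def test_variance_conservation(self, rng):
        img = make_raster(rng.random((4, 10, 10)))
        m = fit_pca(img)
        total = img.values.reshape(4, -1).var(axis=1, ddof=1).sum()
        assert m.explained_variance.sum() == pytest.approx(total, rel=1e-8)

    def test_rank_deficiency(self, rng):
        b1 = rng.random((6, 6))
        img = make_raster(np.stack([b1, 2 * b1 + 1]))
        m = fit_pca(img)
        assert m.explained_variance[1] == pytest.approx(0.0, abs=1e-20)

    def test_eigen_oracle(self, rng):
        """Explained variances match a brute-force covariance eigendecomposition."""
        img = make_raster(rng.random((4, 5, 10)))  # 50 pixels
        m = fit_pca(img)
        X = img.values.reshape(4, -1)
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(X, ddof=1)))[::-1]
        np.testing.assert_allclose(m.explained_variance, eigvals, rtol=1e-8)

    def test_sign_convention(self, rng):
        img = make_raster(rng.random((4, 10, 10)))
        m = fit_pca(img)
        for j in range(4):
            col = m.loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0


class TestPCAScores:
    def test_mean_pixel_maps_to_zero(self, rng):
        img = make_raster(rng.random((4, 8, 8)))
        m = fit_pca(img)
        scores = (m.band_means - m.band_means) @ m.loadings
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)

    def test_pc1_variance_matches_model(self, rng):
        img = make_raster(rng.random((4, 20, 20)))
        m = fit_pca(img)
        s = pca_scores(img, m)
        assert s.band("PC1").var(ddof=1) == pytest.approx(
            m.explained_variance[0], rel=1e-8)

    def test_reconstruction(self, rng):
        img = make_raster(rng.random((4, 8, 8)))
        m = fit_pca(img)
        s = pca_scores(img, m)
        flat = s.values.reshape(4, -1).T @ m.loadings.T + m.band_means
        np.testing.assert_allclose(flat.T.reshape(img.values.shape),
                                   img.values, atol=1e-8)


class TestPCAChange:
    def test_identical_scores_subtract_zero_divide_one(self, rng):
        s = make_raster(rng.random((4, 6, 6)), names=[f"PC{i}" for i in range(1, 5)])
        np.testing.assert_allclose(pca_change(s, s, "subtract").values, 0.0,
                                   atol=1e-12)
        np.testing.assert_allclose(pca_change(s, s, "divide").values, 1.0,
                                   atol=1e-12)

    def test_orientation_of_metrics(self):
        # pre PC1 = 2, post PC1 = 4: difference runs post-pre, ratio pre/post
        pre = make_raster(np.full((1, 2, 2), 2.0), names=["PC1"])
        post = make_raster(np.full((1, 2, 2), 4.0), names=["PC1"])
        assert pca_change(pre, post, "subtract").values[0, 0, 0] == 2.0
        assert pca_change(pre, post, "divide").values[0, 0, 0] == 0.5

    def test_divide_guard(self):
        pre = make_raster(np.ones((1, 2, 2)), names=["PC1"])
        post = make_raster(np.zeros((1, 2, 2)), names=["PC1"])
        out = pca_change(pre, post, "divide")
        assert np.isnan(out.values).all()


class TestFocalStats:
    def test_constant(self):
        r = make_raster(np.full((1, 5, 5), 3.0))
        np.testing.assert_allclose(focal_stats(r, "mean").values, 3.0)
        np.testing.assert_allclose(focal_stats(r, "std").values, 0.0, atol=1e-12)

    def test_single_one_in_zeros(self):
        vals = np.zeros((7, 7))
        vals[3, 3] = 1.0
        out = focal_stats(make_raster(vals), "mean").values[0]
        np.testing.assert_allclose(out[2:5, 2:5], 1.0 / 9)

    @pytest.mark.parametrize("stat", ["mean", "std"])
    def test_brute_force_oracle(self, stat, rng):
        vals = rng.random((10, 10))
        vals[2, 3] = np.nan  # nodata-aware path included
        out = focal_stats(make_raster(vals), stat).values[0]
        expected = brute_force_focal(vals, stat)
        np.testing.assert_allclose(out, expected, atol=1e-12)


class TestSpectralIndices:
    def _pair(self, pre_vals, post_vals):
        names = ["B", "G", "R", "NIR", "SWIR"]
        return ScenePair(make_raster(pre_vals, names=names),
                         make_raster(post_vals, names=names))

    def test_no_change_identities(self, rng):
        vals = rng.random((5, 4, 4)) + 0.1
        idx = spectral_indices(self._pair(vals, vals.copy()))
        np.testing.assert_allclose(idx.band("dNBR"), 0.0, atol=1e-12)
        np.testing.assert_allclose(idx.band("RBR"), 0.0, atol=1e-12)

    def test_ndvi_zero_when_nir_equals_red(self):
        vals = np.full((5, 2, 2), 0.3)
        idx = spectral_indices(self._pair(vals, vals))
        np.testing.assert_allclose(idx.band("NDVI"), 0.0, atol=1e-12)

    def test_rbr_direct_evaluation(self):
        # NBR_pre = 0.5, NBR_post = 0.1 -> dNBR 0.4, RBR = 0.4/1.501
        pre = np.zeros((5, 1, 1))
        pre[3], pre[4] = 0.3, 0.1  # NIR, SWIR -> NBR 0.5
        post = np.zeros((5, 1, 1))
        post[3], post[4] = 0.11, 0.09  # NBR 0.1
        idx = spectral_indices(self._pair(pre, post))
        assert idx.band("dNBR")[0, 0] == pytest.approx(0.4, abs=1e-12)
        assert idx.band("RBR")[0, 0] == pytest.approx(0.4 / 1.501, abs=1e-12)

    def test_bounds(self, rng):
        pre = rng.random((5, 10, 10)) + 0.01
        post = rng.random((5, 10, 10)) + 0.01
        idx = spectral_indices(self._pair(pre, post))
        ndvi = idx.band("NDVI")
        assert np.all(ndvi >= -1) and np.all(ndvi <= 1)
        assert np.isfinite(idx.band("RBR")).all()


class TestComposePredictors:
    @pytest.fixture()
    def stack(self, small_scene):
        pair = ScenePair(small_scene.pre, small_scene.post)
        return compose_predictors(pair)

    def test_eighteen_bands_in_documented_order(self, stack):
        assert len(stack.band_meta) == 18
        sources = [m["source"] for m in stack.band_meta]
        assert sources[:4] == ["focal_mean_pcasub"] * 4
        assert sources[4:8] == ["focal_std_pcasub"] * 4
        assert sources[8:12] == ["focal_mean_pcadiv"] * 4
        assert sources[12:16] == ["focal_std_pcadiv"] * 4
        assert sources[16:] == ["RBR", "NDVI"]
        assert [m["rank"] for m in stack.band_meta] == list(range(1, 19))

    def test_rbr_band_matches_indices(self, stack, small_scene):
        pair = ScenePair(small_scene.pre, small_scene.post)
        rbr = spectral_indices(pair).band("RBR")
        np.testing.assert_array_equal(stack.raster.band("RBR"), rbr)

    def test_visualization_triple_by_name(self, stack):
        trio = stack.raster.select(["NDVI", "RBR", "focal_std_pcasub_pc1"])
        assert trio.n_bands == 3

    def test_missing_swir_gives_17_bands(self, small_scene):
        pre = small_scene.pre.select(["B", "G", "R", "NIR"])
        post = small_scene.post.select(["B", "G", "R", "NIR"])
        with pytest.warns(UserWarning, match="SWIR"):
            stack = compose_predictors(ScenePair(pre, post))
        assert len(stack.band_meta) == 17


class TestPruneCorrelated:
    def _stack_from(self, planes, rng=None):
        arr = np.stack(planes)
        names = [f"p{i}" for i in range(len(planes))]
        raster = make_raster(arr, names=names)
        meta = [{"name": n, "source": "x", "component": 0, "rank": i + 1}
                for i, n in enumerate(names)]
        return PredictorStack(raster, meta)

    def test_duplicate_band_lower_priority_flagged(self, rng):
        b = rng.random((20, 20))
        planes = [b] + [rng.random((20, 20)) for _ in range(8)] + [b.copy()]
        stack = prune_correlated(self._stack_from(planes))
        assert stack.kept[0] and not stack.kept[9]

    def test_independent_noise_all_kept(self):
        rng = np.random.default_rng(1234)
        planes = [rng.standard_normal((100, 100)) for _ in range(18)]
        stack = prune_correlated(self._stack_from(planes))
        assert stack.kept.all()

    def test_threshold_zero_only_first_survives(self, rng):
        planes = [rng.random((30, 30)) for _ in range(5)]
        stack = prune_correlated(self._stack_from(planes), threshold=0.0)
        assert stack.kept.tolist() == [True, False, False, False, False]

    def test_constant_band_warns_and_kept(self, rng):
        planes = [rng.random((10, 10)), np.ones((10, 10)), rng.random((10, 10))]
        with pytest.warns(UserWarning, match="constant"):
            stack = prune_correlated(self._stack_from(planes))
        assert stack.kept[1]
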