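"""Affine / thin-plate-spline estimation, composition and image warping."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spotfuse.errors import TransformError
from spotfuse.registration import (
    AffineTransform2D,
    ChainedTransform,
    LandmarkSet,
    TPSTransform,
    apply_transform,
    compose,
    estimate_transform,
    load_transform,
    transform_from_dict,
    transform_image,
)


def random_affine(seed):
    rng = np.random.default_rng(seed)
    while True:
        A = rng.normal(0, 1, (2, 2)) + np.eye(2)
        if abs(np.linalg.det(A)) > 0.2:
            break
    M = np.eye(3)
    M[:2, :2] = A
    M[:2, 2] = rng.uniform(-50, 50, 2)
    return AffineTransform2D(M)


def landmarks_from_affine(t, n, seed, frame_kwargs=None):
    rng = np.random.default_rng(seed)
    src = rng.uniform(0, 100, (n, 2))
    return LandmarkSet(src, t.apply(src), **(frame_kwargs or {}))


class TestAffineEstimation:
    def test_identity_pairs_give_identity(self):
        src = np.array([[0, 0], [10, 0], [0, 10], [10, 10.0]])
        t = estimate_transform(LandmarkSet(src, src), "affine")
        np.testing.assert_allclose(t.matrix, np.eye(3), atol=1e-12)

    def test_pure_translation(self):
        src = np.array([[0, 0], [10, 0], [0, 10], [5, 5.0]])
        t = estimate_transform(LandmarkSet(src, src + [10, 5]), "affine")
        np.testing.assert_allclose(t.matrix[:2, :2], np.eye(2), atol=1e-12)
        np.testing.assert_allclose(t.matrix[:2, 2], [10, 5], atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_recovery_matches_normal_equations(self, seed):
        gen = random_affine(seed)
        lm = landmarks_from_affine(gen, 8, seed + 100)
        t = estimate_transform(lm, "affine")
        # independent oracle: solve the normal equations directly
        X = np.column_stack([lm.source, np.ones(8)])
        beta = np.linalg.solve(X.T @ X, X.T @ lm.target)
        M = np.eye(3)
        M[:2, :2] = beta[:2].T
        M[:2, 2] = beta[2]
        np.testing.assert_allclose(t.matrix, M, atol=1e-9)
        rel = np.abs(t.matrix - gen.matrix).max() / np.abs(gen.matrix).max()
        assert rel < 1e-8

    def test_matches_skimage_estimate(self):
        from skimage.transform import AffineTransform as SkAffine

        gen = random_affine(42)
        rng = np.random.default_rng(0)
        src = rng.uniform(0, 100, (12, 2))
        t = estimate_transform(LandmarkSet(src, gen.apply(src)), "affine")
        sk = SkAffine.from_estimate(src, gen.apply(src))
        np.testing.assert_allclose(t.matrix, sk.params, atol=1e-8)

    def test_collinear_fatal(self):
        src = np.array([[0, 0], [1, 1], [2, 2], [3, 3.0]])
        with pytest.raises(TransformError, match="collinear"):
            estimate_transform(LandmarkSet(src, src + 1), "affine")

    def test_too_few_pairs_fatal(self):
        with pytest.raises(TransformError, match="3"):
            LandmarkSet(np.zeros((2, 2)) + [[0, 0], [1, 0]], np.ones((2, 2)))


class TestTPS:
    @pytest.mark.parametrize("seed", range(5))
    def test_interpolates_control_points(self, seed):
        rng = np.random.default_rng(seed)
        src = rng.uniform(0, 100, (7, 2))
        tgt = src + rng.normal(0, 10, (7, 2))
        t = TPSTransform.fit(src, tgt)
        np.testing.assert_allclose(t.apply(src), tgt, atol=1e-6)

    def test_affine_pairs_reproduce_affine_on_grid(self):
        gen = random_affine(7)
        lm = landmarks_from_affine(gen, 8, 7)
        t = estimate_transform(lm, "tps")
        gx, gy = np.meshgrid(np.linspace(10, 90, 15), np.linspace(10, 90, 15))
        grid = np.column_stack([gx.ravel(), gy.ravel()])
        np.testing.assert_allclose(t.apply(grid), gen.apply(grid), atol=1e-6)

    def test_matches_skimage_tps(self):
        from skimage.transform import ThinPlateSplineTransform

        rng = np.random.default_rng(11)
        src = rng.uniform(0, 100, (9, 2))
        tgt = src + rng.normal(0, 8, (9, 2))
        t = TPSTransform.fit(src, tgt)
        sk = ThinPlateSplineTransform.from_estimate(src, tgt)
        pts = rng.uniform(10, 90, (40, 2))
        # same spline, different solver conditioning: agree to ~1e-4
        np.testing.assert_allclose(t.apply(pts), sk(pts), atol=1e-4)

    def test_needs_four_pairs(self):
        src = np.array([[0, 0], [1, 0], [0, 1.0]])
        with pytest.raises(TransformError, match="4"):
            estimate_transform(LandmarkSet(src, src), "tps")

    def test_collinear_fatal(self):
        src = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(TransformError, match="collinear"):
            TPSTransform.fit(src, src)


class TestCompose:
    def test_translation_composition(self):
        a = AffineTransform2D(np.array([[1, 0, 1], [0, 1, 0], [0, 0, 1.0]]),
                              "a", "b")
        b = AffineTransform2D(np.array([[1, 0, 0], [0, 1, 1], [0, 0, 1.0]]),
                              "b", "c")
        c = compose(b, a)
        assert isinstance(c, AffineTransform2D)
        np.testing.assert_allclose(c.apply([[0, 0]]), [[1, 1]])
        assert (c.domain_frame, c.codomain_frame) == ("a", "c")

    def test_identity_is_neutral(self):
        t = random_affine(3)
        ident = AffineTransform2D.identity(t.domain_frame)
        pts = np.random.default_rng(0).uniform(0, 10, (5, 2))
        np.testing.assert_allclose(compose(t, ident).apply(pts), t.apply(pts))

    @given(st.integers(0, 50))
    def test_associativity(self, seed):
        a, b, c = (random_affine(seed * 3 + i) for i in range(3))
        for t in (a, b, c):
            t.domain_frame = t.codomain_frame = "f"
        pts = np.random.default_rng(seed).uniform(-10, 10, (6, 2))
        left = compose(compose(a, b), c).apply(pts)
        right = compose(a, compose(b, c)).apply(pts)
        np.testing.assert_allclose(left, right, atol=1e-9)

    def test_frame_mismatch_fatal(self):
        a = AffineTransform2D(np.eye(3), "a", "b")
        c = AffineTransform2D(np.eye(3), "c", "d")
        with pytest.raises(TransformError, match="'b'"):
            compose(c, a)

    def test_tps_chain_equals_direct_with_identity_middle(self):
        gen = random_affine(9)
        lm = landmarks_from_affine(gen, 10, 9)
        direct = estimate_transform(lm, "tps")
        ident_pairs = LandmarkSet(
            lm.source, lm.source, source_frame="msi_native", target_frame="mid"
        )
        second = LandmarkSet(
            lm.source, lm.target, source_frame="mid", target_frame="fullres"
        )
        chained = compose(
            estimate_transform(second, "tps"), estimate_transform(ident_pairs, "tps")
        )
        assert isinstance(chained, ChainedTransform)
        gx, gy = np.meshgrid(np.linspace(20, 80, 10), np.linspace(20, 80, 10))
        grid = np.column_stack([gx.ravel(), gy.ravel()])
        np.testing.assert_allclose(chained.apply(grid), direct.apply(grid), atol=1e-6)


class TestApply:
    def test_identity_unchanged(self):
        pts = np.random.default_rng(0).uniform(0, 100, (20, 2))
        np.testing.assert_array_equal(
            apply_transform(AffineTransform2D.identity(), pts), pts
        )

    def test_permutation_equivariant(self):
        t = random_affine(13)
        pts = np.random.default_rng(1).uniform(0, 100, (30, 2))
        perm = np.random.default_rng(2).permutation(30)
        np.testing.assert_allclose(t.apply(pts)[perm], t.apply(pts[perm]))


class TestTransformImage:
    def test_identity_preserves_content(self):
        img = np.random.default_rng(0).uniform(0, 255, (20, 30))
        out, valid = transform_image(img, AffineTransform2D.identity(), (20, 30))
        np.testing.assert_allclose(out, img, atol=1e-9)
        assert valid.all()

    def test_integer_translation_shifts_exactly(self):
        img = np.zeros((10, 10))
        img[2, 3] = 100.0
        M = np.eye(3)
        M[:2, 2] = [4, 1]  # x (col) +4, y (row) +1
        out, _ = transform_image(img, AffineTransform2D(M, "a", "a"), (10, 10))
        assert out[3, 7] == pytest.approx(100.0)
        assert out.sum() == pytest.approx(100.0)

    def test_warp_then_inverse_recovers_smooth_image(self):
        gx, gy = np.meshgrid(np.arange(60), np.arange(50))
        img = 128 + 100 * np.sin(gx / 12.0) * np.cos(gy / 9.0)
        t = AffineTransform2D(
            np.array([[0.97, 0.05, 3.0], [-0.04, 1.02, -2.0], [0, 0, 1.0]]), "a", "a"
        )
        fwd, _ = transform_image(img, t, (50, 60))
        back, valid = transform_image(fwd, t.inverse(), (50, 60))
        interior = np.zeros_like(valid)
        interior[8:-8, 8:-8] = True
        err = np.abs(back - img)[valid & interior]
        assert err.mean() < 2.0

    def test_singular_affine_fatal(self):
        with pytest.raises(TransformError, match="singular"):
            AffineTransform2D(np.array([[1, 0, 0], [1, 0, 0], [0, 0, 1.0]]))


class TestSerialization:
    @pytest.mark.parametrize("kind", ["affine", "tps"])
    def test_json_roundtrip(self, kind, tmp_path):
        gen = random_affine(17)
        lm = landmarks_from_affine(gen, 6, 17)
        t = estimate_transform(lm, kind)
        t.to_json(tmp_path / "t.json")
        back = load_transform(tmp_path / "t.json")
        pts = np.random.default_rng(3).uniform(0, 100, (10, 2))
        np.testing.assert_allclose(back.apply(pts), t.apply(pts), atol=1e-12)
        assert back.kind == kind

    def test_chained_roundtrip(self):
        a = random_affine(19)
        a.codomain_frame = "mid"
        lm = landmarks_from_affine(
            random_affine(20), 6, 20,
            frame_kwargs={"source_frame": "mid", "target_frame": "fullres"},
        )
        chain = compose(estimate_transform(lm, "tps"), a)
        back = transform_from_dict(chain.to_dict())
        pts = np.random.default_rng(4).uniform(0, 50, (8, 2))
        np.testing.assert_allclose(back.apply(pts), chain.apply(pts), atol=1e-12)
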