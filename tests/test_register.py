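import numpy as np
import pytest

from rnfltex.register import (
    LandmarkSet,
    QuadraticLandmarkTransform,
    QuadraticTransform,
    SingularLandmarkError,
    apply_transform,
    chessboard,
    fit_transform,
    invert_points,
    residual_energy,
    warp_image,
)

from oracles import normal_equations_fit, quadratic_map_oracle


def _random_transform(rng, quad_scale=1e-4):
    a = np.zeros((2, 6))
    a[0, 3], a[1, 4] = 1.0, 1.0
    a[:, 3:5] += rng.uniform(-0.05, 0.05, (2, 2))
    a[:, 5] = rng.uniform(-10, 10, 2)
    a[:, 0:3] = rng.uniform(-quad_scale, quad_scale, (2, 3))
    return QuadraticTransform(a)


def _grid_points(n_side=4, extent=100.0):
    g = np.linspace(0, extent, n_side)
    return np.array([(x, y) for y in g for x in g])


class TestApplyTransform:
    def test_identity_leaves_points(self, rng):
        pts = rng.uniform(-50, 50, (20, 2))
        np.testing.assert_array_equal(
            apply_transform(QuadraticTransform.identity(), pts), pts
        )

    def test_pure_translation(self, rng):
        t = QuadraticTransform.identity()
        t.a[0, 5], t.a[1, 5] = 7.5, -3.25
        pts = rng.uniform(0, 100, (10, 2))
        np.testing.assert_allclose(apply_transform(t, pts), pts + [7.5, -3.25])

    def test_matches_monomial_oracle(self, rng):
        t = _random_transform(rng, quad_scale=1e-3)
        pts = rng.uniform(-20, 120, (30, 2))
        np.testing.assert_allclose(
            apply_transform(t, pts), quadratic_map_oracle(t.a, pts), atol=1e-9
        )


class TestFitTransform:
    def test_identity_landmarks_give_identity(self, rng):
        pts = _grid_points()
        t = fit_transform(LandmarkSet(pts, pts))
        expected = QuadraticTransform.identity().a
        np.testing.assert_allclose(t.a, expected, atol=1e-10)
        assert residual_energy(t, LandmarkSet(pts, pts)) < 1e-18

    def test_exact_recovery_of_known_quadratic(self, rng):
        truth = _random_transform(rng)
        src = _grid_points(4)  # 16 exact correspondences
        lm = LandmarkSet(src, apply_transform(truth, src))
        t = fit_transform(lm)
        assert np.abs(t.a - truth.a).max() <= 1e-8
        # independent route: explicit normal equations give the same minimizer
        np.testing.assert_allclose(t.a, normal_equations_fit(src, lm.reference), atol=1e-8)

    def test_residual_energy_equals_bruteforce_sum(self, rng):
        src = _grid_points(4)
        dst = apply_transform(_random_transform(rng), src) + rng.normal(0, 1.0, src.shape)
        lm = LandmarkSet(src[:12], dst[:12])  # protocol-default 12 landmarks
        t = fit_transform(lm)
        mapped = quadratic_map_oracle(t.a, lm.floating)
        brute = sum(
            (mx - X) ** 2 + (my - Y) ** 2
            for (mx, my), (X, Y) in zip(mapped, lm.reference)
        )
        assert residual_energy(t, lm) == pytest.approx(brute, rel=1e-12)

    def test_quadratic_energy_never_exceeds_affine(self, rng):
        src = _grid_points(5)
        dst = apply_transform(_random_transform(rng), src) + rng.normal(0, 2.0, src.shape)
        lm = LandmarkSet(src, dst)
        e_quad = residual_energy(fit_transform(lm, "quadratic"), lm)
        e_aff = residual_energy(fit_transform(lm, "affine"), lm)
        assert e_quad <= e_aff + 1e-9

    def test_too_few_landmarks_raises(self, rng):
        pts = rng.uniform(0, 100, (5, 2))
        with pytest.raises(SingularLandmarkError, match="at least 6"):
            fit_transform(LandmarkSet(pts, pts))

    def test_collinear_landmarks_raise_singularity(self):
        x = np.linspace(0, 100, 8)
        pts = np.column_stack([x, 2 * x + 1])
        with pytest.raises(SingularLandmarkError, match="rank-deficient"):
            fit_transform(LandmarkSet(pts, pts))

    def test_equivariant_under_origin_shift(self, rng):
        # shifting both coordinate frames by the same offset must shift the
        # fitted mapping accordingly: t'(p) = t(p - d) + d
        truth = _random_transform(rng)
        src = _grid_points(4)
        dst = apply_transform(truth, src) + rng.normal(0, 0.5, src.shape)
        d = np.array([37.0, -12.0])
        t0 = fit_transform(LandmarkSet(src, dst))
        t1 = fit_transform(LandmarkSet(src + d, dst + d))
        probe = rng.uniform(0, 100, (12, 2))
        np.testing.assert_allclose(
            apply_transform(t1, probe + d), apply_transform(t0, probe) + d, atol=1e-6
        )

    def test_jitter_gives_comparable_mean_residual(self, rng):
        # with i.i.d. landmark jitter of s px, the per-landmark residual is
        # on the order of s (the fit absorbs some noise: 12 dof / 2N coords)
        s = 1.5
        truth = _random_transform(rng)
        src = _grid_points(6, extent=300.0)
        dst = apply_transform(truth, src) + rng.normal(0, s, src.shape)
        lm = LandmarkSet(src, dst)
        t = fit_transform(lm)
        mean_resid = np.sqrt(
            ((apply_transform(t, src) - dst) ** 2).sum(axis=1)
        ).mean()
        assert 0.3 * s < mean_resid < 2.0 * s

    def test_serialization_roundtrip_carries_12_coefficients(self, rng):
        t = _random_transform(rng)
        text = t.to_json()
        back = QuadraticTransform.from_json(text)
        np.testing.assert_array_equal(back.a, t.a)
        import json

        assert len(json.loads(text)["a"]) == 12


class TestInverseAndWarp:
    def test_invert_points_roundtrip(self, rng):
        t = _random_transform(rng)
        pts = rng.uniform(0, 200, (50, 2))
        mapped = apply_transform(t, pts)
        back, ok = invert_points(t, mapped)
        assert ok.all()
        np.testing.assert_allclose(back, pts, atol=1e-5)

    def test_identity_warp_preserves_image(self, rng):
        img = rng.uniform(0, 1, (40, 40))
        warped, valid = warp_image(img, QuadraticTransform.identity(), img.shape)
        assert valid.all()
        np.testing.assert_allclose(warped, img, atol=1e-9)

    def test_translation_warp_marks_outside_invalid(self, rng):
        t = QuadraticTransform.identity()
        t.a[0, 5] = 10.0  # reference x = floating x + 10
        img = rng.uniform(0, 1, (30, 30))
        warped, valid = warp_image(img, t, img.shape)
        assert not valid[:, :9].any()  # left band has no preimage
        assert valid[:, 15:].all()
        np.testing.assert_allclose(warped[:, 15:], img[:, 5:20], atol=1e-9)

    def test_warped_slo_landmarks_align_on_fundus(self, small_scene):
        # registration ground truth: mapping the floating landmarks through
        # the fitted transform must land on the reference landmarks < 0.5 px
        flo, ref = small_scene.landmarks
        est = QuadraticLandmarkTransform().fit(flo, ref)
        np.testing.assert_allclose(est.transform(flo), ref, atol=0.5)
        assert np.abs(est.coef_ - small_scene.true_warp.a).max() < 1e-8

    def test_chessboard_alternates_sources(self):
        a, b = np.zeros((64, 64)), np.ones((64, 64))
        cb = chessboard(a, b, tile_px=16)
        assert cb[0, 0] == 0 and cb[0, 16] == 1 and cb[16, 16] == 0


class TestEstimatorApi:
    def test_fit_sets_sklearn_style_attributes(self, rng):
        truth = _random_transform(rng)
        src = _grid_points(4)
        est = QuadraticLandmarkTransform(kind="quadratic")
        est.fit(src, apply_transform(truth, src))
        assert est.coef_.shape == (2, 6)
        assert est.n_landmarks_ == 16
        assert est.energy_ < 1e-12
        assert est.get_params()["kind"] == "quadratic"

    def test_inverse_transform_roundtrip(self, rng):
        truth = _random_transform(rng)
        src = _grid_points(4)
        est = QuadraticLandmarkTransform().fit(src, apply_transform(truth, src))
        pts = rng.uniform(10, 90, (8, 2))
        np.testing.assert_allclose(
            est.inverse_transform(est.transform(pts)), pts, atol=1e-5
        )

    def test_unfitted_estimator_raises(self):
        with pytest.raises(AttributeError, match="not fitted"):
            QuadraticLandmarkTransform().transform([[0.0, 0.0]])
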