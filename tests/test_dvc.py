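import numpy as np
import pytest

from conftest import LinearImageClassifier
from retcf.diffusion import DenoisingDiffusion, NoisyState
from retcf.dvc import (GuidanceConfig, cone_project, distance_gradient,
                       generate_dvc, generate_dvc_batch, guidance_gradient,
                       total_shift, SHIFT_TO_NOISE)


def angle_deg(a, b):
    ca = float(a.ravel() @ b.ravel()) / (np.linalg.norm(a) * np.linalg.norm(b))
    return np.degrees(np.arccos(np.clip(ca, -1, 1)))


class TestConeProjection:
    def test_parallel_vector_unchanged(self):
        g = np.array([2.0, 0.0])
        np.testing.assert_allclose(cone_project(g, np.array([5.0, 0.0]), 30), g)

    def test_vector_inside_cone_unchanged(self):
        p = np.array([1.0, 0.0])
        r = np.array([1.0, 0.3])  # ~16.7 degrees
        np.testing.assert_allclose(cone_project(r, p, 30), r)

    def test_orthogonal_at_45_degrees(self):
        out = cone_project(np.array([0.0, 1.0]), np.array([1.0, 0.0]), 45.0)
        np.testing.assert_allclose(out, [0.5, 0.5], atol=1e-12)

    def test_polar_cone_maps_to_zero(self):
        out = cone_project(np.array([-1.0, 0.0]), np.array([1.0, 0.0]), 30.0)
        np.testing.assert_allclose(out, [0.0, 0.0])

    def test_projection_satisfies_cone_constraint(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            r = rng.normal(size=4)
            p = rng.normal(size=4)
            alpha = float(rng.uniform(5, 85))
            out = cone_project(r, p, alpha)
            if np.linalg.norm(out) > 1e-9:
                assert angle_deg(out, p) <= alpha + 1e-6

    def test_zero_plain_gradient_falls_back_with_warning(self, caplog):
        r = np.array([1.0, 2.0])
        with caplog.at_level("WARNING"):
            out = cone_project(r, np.zeros(2), 30.0)
        np.testing.assert_array_equal(out, r)
        assert any("zero plain gradient" in m for m in caplog.messages)

    def test_shape_preserved_for_images(self):
        rng = np.random.default_rng(0)
        r = rng.normal(size=(3, 4, 4))
        p = rng.normal(size=(3, 4, 4))
        assert cone_project(r, p, 30.0).shape == (3, 4, 4)


@pytest.fixture(scope="module")
def tiny_diffusion():
    rng = np.random.default_rng(0)
    dm = DenoisingDiffusion(T=20, base_channels=2, n_iter=5, batch_size=2,
                            random_state=0)
    dm.fit(rng.uniform(0, 1, (4, 1, 8, 8)).astype(np.float32))
    return dm


class TestGuidanceGradient:
    def test_uniform_classifier_gives_zero_gradient(self, tiny_diffusion):
        clf = LinearImageClassifier(np.zeros((3, 64), dtype=np.float32))
        x_t = np.random.default_rng(1).normal(0, 0.3, (2, 1, 8, 8)).astype(np.float32)
        g = guidance_gradient(tiny_diffusion, {"plain": clf},
                              NoisyState(x_t=x_t, t=10), k=0,
                              config=GuidanceConfig(target_class=0, mode="plain"))
        np.testing.assert_allclose(g, 0.0, atol=1e-8)

    def test_linear_logit_closed_form_without_denoiser_jacobian(self):
        """With a zero-output denoiser, eps is constant in x_t and the chain
        reduces to the analytic softmax gradient scaled by d x0_hat/d x_t."""
        rng = np.random.default_rng(2)

        class ZeroEps:
            def __init__(self, sched):
                self.schedule_ = sched

            def predict_eps(self, x_t, t):
                return np.zeros_like(x_t)

            def eps_vjp(self, cot):
                return np.zeros_like(cot)

        from retcf.diffusion import default_schedule
        dm = ZeroEps(default_schedule(20))
        W = rng.normal(0, 1, (2, 64)).astype(np.float32)
        clf = LinearImageClassifier(W)
        x_t = rng.normal(0, 0.2, (1, 1, 8, 8)).astype(np.float32)
        t = 8
        g = guidance_gradient(dm, {"plain": clf}, NoisyState(x_t=x_t, t=t), k=1,
                              config=GuidanceConfig(target_class=1, mode="plain"))
        ab = float(dm.schedule_.alpha_bar(t))
        x0h = x_t / np.sqrt(ab)
        z = ((x0h.reshape(1, -1) + 1) / 2) @ W.T
        from retcf.nn import softmax
        p = softmax(z)
        d = -p.copy()
        d[0, 1] += 1
        expected = (d @ W).reshape(x_t.shape) * 0.5 / np.sqrt(ab)
        np.testing.assert_allclose(g, expected, rtol=2e-5, atol=1e-7)

    def test_bad_target_class_rejected(self, tiny_diffusion):
        clf = LinearImageClassifier(np.zeros((2, 64), dtype=np.float32))
        with pytest.raises(ValueError, match="target class"):
            guidance_gradient(tiny_diffusion, {"plain": clf},
                              NoisyState(x_t=np.zeros((1, 1, 8, 8),
                                                      dtype=np.float32), t=5),
                              k=7, config=GuidanceConfig(mode="plain"))


class TestDistanceGradient:
    def test_zero_at_the_original(self):
        x = np.random.default_rng(0).normal(size=(2, 1, 4, 4)).astype(np.float32)
        g = distance_gradient(x, x, lambda_d=1.0)
        np.testing.assert_allclose(g, 0.0)

    def test_linear_in_lambda(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(1, 1, 4, 4)).astype(np.float32)
        b = rng.normal(size=(1, 1, 4, 4)).astype(np.float32)
        g1 = distance_gradient(a, b, lambda_d=0.5)
        g2 = distance_gradient(a, b, lambda_d=1.0)
        np.testing.assert_allclose(2 * g1, g2, rtol=1e-6)
        assert np.allclose(distance_gradient(a, b, 0.0), 0.0)

    def test_points_back_toward_the_original(self):
        a = np.ones((1, 1, 2, 2), dtype=np.float32)
        b = np.zeros((1, 1, 2, 2), dtype=np.float32)
        g = distance_gradient(a, b, 1.0)
        assert np.all(g < 0)


class TestTotalShift:
    def test_zero_gradients_give_zero_shift(self):
        from retcf.diffusion import default_schedule
        s = default_schedule(50)
        z = np.zeros((1, 1, 4, 4), dtype=np.float32)
        out = total_shift(z, z, s, 10, GuidanceConfig())
        np.testing.assert_allclose(out, 0.0)

    def test_orthogonal_unit_gradients_hand_norm(self):
        from retcf.diffusion import default_schedule
        s = default_schedule(50)
        g1 = np.zeros((1, 1, 2, 2), dtype=np.float32)
        g2 = np.zeros((1, 1, 2, 2), dtype=np.float32)
        g1[0, 0, 0, 0] = 1.0
        g2[0, 0, 1, 1] = 1.0
        cfg = GuidanceConfig(lambda_d=1.0, guidance_scale=1.0)
        out = total_shift(g1, g2, s, 20, cfg)
        scale = SHIFT_TO_NOISE * np.sqrt(float(s.posterior_variance(20)))
        assert np.linalg.norm(out) == pytest.approx(np.sqrt(2.0) * scale, rel=1e-5)

    def test_no_distance_term_keeps_guidance_direction(self):
        from retcf.diffusion import default_schedule
        s = default_schedule(50)
        rng = np.random.default_rng(3)
        g = rng.normal(size=(1, 1, 4, 4)).astype(np.float32)
        out = total_shift(g, np.zeros_like(g), s, 5,
                          GuidanceConfig(lambda_d=0.0))
        cos = float(out.ravel() @ g.ravel()) / (np.linalg.norm(out) * np.linalg.norm(g))
        assert cos == pytest.approx(1.0, abs=1e-6)


class TestGenerateDvc:
    @pytest.fixture(scope="class")
    def setup(self, toy_classifiers):
        clfs, (X, y) = toy_classifiers
        rng = np.random.default_rng(0)
        dm = DenoisingDiffusion(T=30, base_channels=2, n_iter=60, batch_size=8,
                                random_state=0)
        dm.fit(X[::4])
        return dm, clfs, X, y

    def test_seeded_repeat_is_identical(self, setup):
        dm, clfs, X, y = setup
        cfg = GuidanceConfig(target_class=1, seed=5)
        a = generate_dvc(X[0], 1, dm, clfs, cfg)
        b = generate_dvc(X[0], 1, dm, clfs, cfg)
        np.testing.assert_array_equal(a.image, b.image)
        assert a.target_confidence == b.target_confidence

    def test_strong_regularization_stays_closer(self, setup):
        dm, clfs, X, y = setup
        x0 = X[1]
        near = generate_dvc(x0, 1, dm, clfs, GuidanceConfig(target_class=1,
                                                            lambda_d=50.0, seed=2))
        far = generate_dvc(x0, 1, dm, clfs, GuidanceConfig(target_class=1,
                                                           lambda_d=0.5, seed=2))
        assert near.l2_distance < far.l2_distance

    def test_result_fields_consistent(self, setup):
        dm, clfs, X, y = setup
        res = generate_dvc(X[2], 1, dm, clfs, GuidanceConfig(target_class=1, seed=0))
        assert 0.0 <= res.target_confidence <= 1.0
        probs = clfs["plain"].predict_proba(res.image[None])[0]
        assert res.flipped == (int(np.argmax(probs)) == 1)
        assert res.image.min() >= 0 and res.image.max() <= 1
        assert len(res.confidence_trace) == 15  # ceil(30 * 0.5) guided steps

    def test_incompatible_shape_rejected(self, setup):
        dm, clfs, X, y = setup
        with pytest.raises(ValueError, match="shape"):
            generate_dvc_batch(np.zeros((1, 3, 8, 8), dtype=np.float32), 1,
                               dm, clfs, GuidanceConfig(target_class=1))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GuidanceConfig(lambda_d=-1)
        with pytest.raises(ValueError):
            GuidanceConfig(cone_alpha_deg=95)
        with pytest.raises(ValueError):
            GuidanceConfig(start_fraction=0.0)
        with pytest.raises(ValueError):
            GuidanceConfig(mode="hybrid")
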