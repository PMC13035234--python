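"""Loss components, penalties, optimizer behavior, and end-to-end training."""

import copy

import numpy as np
import pytest

from phosphodyn import trainer as tr
from phosphodyn.model import ModelConfig, PhosphoModel
from phosphodyn.trainer import (TrainingConfig, masked_mse, masked_mse_grad,
                                sign_violation_penalty, smooth_clip,
                                spectral_penalty, train)


class TestMaskedMSE:
    def test_perfect_prediction(self):
        x = np.arange(6.0).reshape(2, 3)
        assert masked_mse(x, x, np.ones_like(x)) == 0.0

    def test_hand_computed(self):
        pred = np.array([1.0, 3.0])
        obs = np.array([0.0, 0.0])
        mask = np.array([True, False])
        assert masked_mse(pred, obs, mask) == 1.0

    def test_all_false_mask_errors(self):
        with pytest.raises(ValueError, match="no observed"):
            masked_mse(np.ones(3), np.ones(3), np.zeros(3, dtype=bool))

    def test_gradient_only_on_observed(self):
        pred = np.array([2.0, 5.0])
        obs = np.zeros(2)
        mask = np.array([True, False])
        g = masked_mse_grad(pred, obs, mask)
        assert g[1] == 0.0 and g[0] == pytest.approx(4.0)


class TestSignPenalty:
    def test_consistent_weights_zero(self):
        sign = np.array([[0, 1], [-1, 0]])
        W = np.array([[0.0, 0.5], [-0.2, 0.0]])
        assert sign_violation_penalty(W, sign) == 0.0

    def test_single_violation(self):
        sign = np.array([[0.0, 1.0], [0.0, 0.0]])
        W = np.array([[0.0, -0.3], [0.0, 0.0]])
        assert sign_violation_penalty(W, sign) == pytest.approx(0.09)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        sign = rng.choice([-1.0, 0.0, 1.0], size=(4, 4))
        W = rng.normal(size=(4, 4))
        pen, grad = sign_violation_penalty(W, sign, return_grad=True)
        eps = 1e-6
        for idx in [(0, 1), (2, 3), (3, 0)]:
            Wp, Wm = W.copy(), W.copy()
            Wp[idx] += eps
            Wm[idx] -= eps
            num = (sign_violation_penalty(Wp, sign)
                   - sign_violation_penalty(Wm, sign)) / (2 * eps)
            assert grad[idx] == pytest.approx(num, abs=1e-6)

    def test_gradient_pushes_violations_toward_zero(self):
        sign = np.array([[0.0, 1.0], [0.0, 0.0]])
        W = np.array([[0.0, -0.3], [0.0, 0.0]])
        _, grad = sign_violation_penalty(W, sign, return_grad=True)
        # descending the penalty raises the violating negative weight
        assert grad[0, 1] < 0


class TestSpectralPenalty:
    def test_zero_matrix(self):
        assert spectral_penalty(np.zeros((3, 3))) == 0.0

    def test_known_excess(self):
        W = np.diag([2.0, 0.0])
        pen = spectral_penalty(W, target=0.95, power_iterations=60)
        assert pen == pytest.approx(1.05**2, rel=1e-3)

    def test_below_target_no_penalty_or_gradient(self):
        W = np.diag([0.3, 0.1])
        pen, grad = spectral_penalty(W, return_grad=True)
        assert pen == 0.0 and np.all(grad == 0)

    def test_descent_drives_radius_estimate_below_target(self):
        rng = np.random.default_rng(0)
        W = rng.normal(scale=0.8, size=(6, 6))
        from phosphodyn.pkn import spectral_radius
        assert spectral_radius(W, 5) > 0.95
        for _ in range(400):
            _, grad = spectral_penalty(W, 0.95, 5, return_grad=True)
            W -= 0.05 * grad
        assert spectral_radius(W, 5) < 0.95 + 1e-3



class TestSmoothClip:
    def test_norm_preserving_below_threshold(self):
        g = np.array([0.03, -0.04])  # |g| = 0.05 << g_max
        clipped = smooth_clip(g, 10.0)
        assert np.linalg.norm(clipped) == pytest.approx(0.05, rel=1e-4)

    def test_bounded_above(self):
        g = np.full(100, 1e4)
        assert np.linalg.norm(smooth_clip(g, 10.0)) <= 10.0

    def test_direction_preserved(self):
        rng = np.random.default_rng(0)
        g = rng.normal(size=7) * 100
        clipped = smooth_clip(g, 1.0)
        cos = g @ clipped / (np.linalg.norm(g) * np.linalg.norm(clipped))
        assert cos == pytest.approx(1.0)


class TestScheduler:
    def test_noise_scales_with_lr(self):
        cfg = TrainingConfig(epochs=100, grad_noise=0.5)
        lr0 = tr.cosine_warm_restart_lr(0, cfg)
        lr_mid = tr.cosine_warm_restart_lr(10, cfg)
        assert lr_mid < lr0  # annealed within the cycle
        # restart: lr returns to the maximum at the cycle boundary
        assert tr.cosine_warm_restart_lr(20, cfg) == pytest.approx(lr0)


class TestTrain:
    def test_smoke_loss_halves(self, small_dataset):
        ds = small_dataset
        model = PhosphoModel(ds.ground_truth.network, ds.site_assignment,
                             ds.design, ds.timecourse.times, ModelConfig(seed=0))
        report = train(model, ds.timecourse, ds.design,
                       TrainingConfig(epochs=300, batch_mode="full",
                                      random_seed=0))
        assert report.mse[-1] < 0.5 * report.mse[0]
        # components sum to total
        assert np.allclose(report.total,
                           report.mse + report.l2 + report.sign + report.spectral)

    def test_zero_learning_rate_leaves_params_unchanged(self, small_dataset):
        ds = small_dataset
        model = PhosphoModel(ds.ground_truth.network, ds.site_assignment,
                             ds.design, ds.timecourse.times,
                             ModelConfig(seed=0, n_steps=20))
        before = copy.deepcopy(model.params)
        train(model, ds.timecourse, ds.design,
              TrainingConfig(epochs=3, learning_rate=0.0, lr_min_fraction=0.0,
                             grad_noise=0.0, random_seed=0))
        for k in before:
            assert np.array_equal(before[k], model.params[k]), k

    def test_same_seed_identical_report(self, small_dataset):
        ds = small_dataset
        reports = []
        for _ in range(2):
            model = PhosphoModel(ds.ground_truth.network, ds.site_assignment,
                                 ds.design, ds.timecourse.times,
                                 ModelConfig(seed=1, n_steps=20))
            reports.append(train(model, ds.timecourse, ds.design,
                                 TrainingConfig(epochs=20, random_seed=5)))
        assert np.array_equal(reports[0].total, reports[1].total)

    def test_nan_loss_aborts_with_component_name(self, small_dataset):
        ds = small_dataset
        model = PhosphoModel(ds.ground_truth.network, ds.site_assignment,
                             ds.design, ds.timecourse.times,
                             ModelConfig(seed=0, n_steps=10))
        model.params["b"][0] = np.inf
        with pytest.raises((FloatingPointError, ValueError)):
            train(model, ds.timecourse, ds.design,
                  TrainingConfig(epochs=2, random_seed=0))

    def test_parameter_recovery_positive_correlation(self, small_dataset):
        """Trained edge weights correlate with the generating weights."""
        ds = small_dataset
        gt = ds.ground_truth
        model = PhosphoModel(gt.network, ds.site_assignment, ds.design,
                             ds.timecourse.times, ModelConfig(seed=0))
        train(model, ds.timecourse, ds.design,
              TrainingConfig(epochs=400, batch_mode="full", random_seed=0))
        support = gt.network.adjacency_mask.astype(bool)
        r = np.corrcoef(model.effective_weights()[support],
                        gt.weights[support])[0, 1]
        assert r > 0.2

    def test_full_model_gradient_matches_finite_differences(self, small_dataset):
        ds = small_dataset
        model = PhosphoModel(ds.ground_truth.network, ds.site_assignment,
                             ds.design, ds.timecourse.times,
                             ModelConfig(seed=0, n_steps=12))
        cfg = TrainingConfig(epochs=1, grad_noise=0.0)
        # keep anchors away from integer steps, where soft indexing has a
        # (benign) kink that finite differences would straddle
        model.params["delta_raw"] = np.random.default_rng(9).normal(
            0.1, 0.3, size=model.times.size)
        model.params["alpha"][0] = 0.37
        model.params["u_raw"][0] = 0.21
        obs, mask = ds.timecourse.values, ds.timecourse.mask
        x = model.build_inputs(ds.design)
        _, grads = tr._batch_loss_and_grads(model, ds.design, x, obs, mask, cfg)
        rng = np.random.default_rng(0)
        eps = 1e-6
        for k, v in model.params.items():
            for _ in range(2):
                idx = tuple(rng.integers(0, s) for s in v.shape)
                orig = v[idx]
                v[idx] = orig + eps
                up, _ = tr._batch_loss_and_grads(
                    model, ds.design, model.build_inputs(ds.design), obs, mask, cfg)
                v[idx] = orig - eps
                dn, _ = tr._batch_loss_and_grads(
                    model, ds.design, model.build_inputs(ds.design), obs, mask, cfg)
                v[idx] = orig
                num = (up["total"] - dn["total"]) / (2 * eps)
                assert grads[k][idx] == pytest.approx(num, rel=5e-3, abs=1e-7), k

    def test_per_sample_batching_runs(self, small_dataset):
        ds = small_dataset
        model = PhosphoModel(ds.ground_truth.network, ds.site_assignment,
                             ds.design, ds.timecourse.times,
                             ModelConfig(seed=0, n_steps=20))
        report = train(model, ds.timecourse, ds.design,
                       TrainingConfig(epochs=10, batch_mode="sample",
                                      random_seed=0))
        assert report.total.size == 10
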