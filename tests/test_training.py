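"""Loss construction, gradients, Dale constraints and evaluation."""

import dataclasses

import numpy as np
import pytest

from ipdnet.network import NetworkParams, log_softmax
from ipdnet.seeding import rng_for
from ipdnet.task import TaskConfig, make_batch, sample_ipds, ipd_to_class, \
    class_to_midpoint
from ipdnet.training import (
    TrainConfig, cross_entropy_loss, rate_regularizer, loss_and_grads,
    train, evaluate, apply_dale_constraint, assign_dale_signs, init_params,
    Adam, _effective, _grad_to_theta,
)


class TestCrossEntropy:
    def test_perfect_prediction_gives_zero(self):
        x = np.log(np.array([[1 - 2e-9, 1e-9, 1e-9]]))
        assert cross_entropy_loss(x, [0]) == pytest.approx(0.0, abs=1e-8)

    def test_uniform_prediction_gives_log_nc(self):
        x = np.full((5, 12), -np.log(12))
        assert cross_entropy_loss(x, [0, 3, 5, 7, 11]) == pytest.approx(np.log(12))

    def test_batch_permutation_invariance(self, rng):
        x = log_softmax(rng.normal(size=(40, 12)))
        k = rng.integers(0, 12, 40)
        perm = rng.permutation(40)
        assert cross_entropy_loss(x, k) == pytest.approx(
            cross_entropy_loss(x[perm], k[perm]))


class TestRateRegularizer:
    duration = 0.1

    def _spikes_at_rate(self, rate):
        """One trial, one neuron, spike count = rate * duration."""
        n = int(rate * self.duration)
        spikes = np.zeros((1, 100, 1))
        spikes[0, :n, 0] = 1.0
        return spikes

    @pytest.mark.parametrize("rate,expected", [
        (200.0, 1.0),    # r_m = r_plus -> L_m = 1
        (100.0, 0.0),    # r_m = r_minus -> contributes nothing
        (150.0, 0.25),   # ((150-100)/(200-100))^2
    ])
    def test_printed_values(self, rate, expected):
        # c=1, single neuron: L = L_m
        val = rate_regularizer(self._spikes_at_rate(rate), self.duration,
                               100.0, 200.0, c=1.0)
        assert val == pytest.approx(expected)

    def test_continuous_at_threshold_and_monotone(self):
        rates = np.linspace(80, 260, 50)
        vals = [rate_regularizer(self._spikes_at_rate(r), self.duration,
                                 100.0, 200.0, 1.0) for r in rates]
        assert np.all(np.diff(vals) >= -1e-12)
        just_above = rate_regularizer(self._spikes_at_rate(101),
                                      self.duration, 100.0, 200.0, 1.0)
        assert just_above < 1e-3


class TestGradients:
    def test_bptt_matches_finite_differences(self):
        """Analytic BPTT gradient vs central finite differences on a toy
        network, with the differentiable spike relaxation in place of the
        step."""
        rng = np.random.default_rng(5)
        task = TaskConfig(n_psi=4, duration=0.02, n_classes=3)
        cfg = TrainConfig(n_hidden=5, n_train=128, batch_size=128,
                          r_minus=10.0, r_plus=50.0)
        params = init_params(task, cfg, rng)
        params.w_ih *= 3  # ensure some units are near threshold
        batch = make_batch(16, task, rng)
        labels = batch.class_true
        losses, grads = loss_and_grads(batch.spikes, labels, params, cfg,
                                       task.dt, soft=True)
        eps = 1e-5
        for name in ("w_ih", "w_ho"):
            w = getattr(params, name)
            idx = np.unravel_index(np.argmax(np.abs(grads[name])), w.shape)
            orig = w[idx]
            w[idx] = orig + eps
            up, _ = loss_and_grads(batch.spikes, labels, params, cfg,
                                   task.dt, soft=True)
            w[idx] = orig - eps
            dn, _ = loss_and_grads(batch.spikes, labels, params, cfg,
                                   task.dt, soft=True)
            w[idx] = orig
            fd = (up["total"] - dn["total"]) / (2 * eps)
            assert grads[name][idx] == pytest.approx(fd, rel=1e-3, abs=1e-9)


class TestDale:
    def test_sign_assignment_fractions(self, rng):
        signs = assign_dale_signs(100, 0.3, rng)
        assert (signs == -1).sum() == 30

    def test_constraint_modes(self, rng, task_small):
        params = init_params(task_small, TrainConfig(n_hidden=4), rng)
        exc = apply_dale_constraint(params, "excitatory_only", rng)
        assert np.all(exc.w_ih >= 0) and np.all(exc.w_ho >= 0)
        inh = apply_dale_constraint(params, "inhibitory_only", rng)
        assert np.all(inh.w_ih <= 0)
        bal = apply_dale_constraint(params, "balanced", rng)
        assert (bal.sign_mask_ih == -1).sum() == task_small.n_inputs // 2

    def test_signs_never_flip_under_optimisation(self, rng):
        """100 Adam steps on random gradients leave every effective weight
        on its assigned side of zero (sign-magnitude parameterisation)."""
        theta = rng.normal(size=(20, 6))
        sign = assign_dale_signs(20, 0.5, rng)
        opt = Adam({"w": theta.shape}, lr=0.05)
        for _ in range(100):
            g_eff = rng.normal(size=theta.shape)
            g = _grad_to_theta(g_eff, theta, sign)
            opt.step({"w": theta}, {"w": g})
            eff = _effective(theta, sign)
            assert np.all(eff * sign[:, None] >= 0)

    def test_inhibitory_only_network_is_silent_and_at_chance(self):
        task = TaskConfig(n_psi=20)
        cfg = TrainConfig(n_hidden=4, dale_mode="inhibitory_only")
        rng = rng_for(0, "dale-test")
        params = apply_dale_constraint(init_params(task, cfg, rng),
                                       "inhibitory_only", rng)
        report = evaluate(params, task, 2048, rng)
        assert report.hidden_rates.sum() == 0.0
        se = np.sqrt((1 / 12) * (11 / 12) / 2048)
        assert abs(report.accuracy - 1 / 12) < 3 * se


@pytest.fixture(scope="module")
def tiny_run():
    task = TaskConfig(n_psi=20, duration=0.05)
    cfg = TrainConfig(n_train=512, batch_size=64, epochs=4,
                      n_hidden=4, seed=11, n_test=512)
    return task, cfg, train(task, cfg)


class TestTrainLoop:
    def test_loss_decreases(self, tiny_run):
        _, _, res = tiny_run
        assert res.loss_history[-1] < res.loss_history[0]

    def test_seeded_determinism(self, tiny_run):
        task, cfg, res = tiny_run
        res2 = train(task, cfg)
        np.testing.assert_allclose(res.loss_history, res2.loss_history,
                                   atol=1e-6)
        np.testing.assert_allclose(res.params.w_ih, res2.params.w_ih,
                                   atol=1e-6)
        assert res.metrics.accuracy == res2.metrics.accuracy

    def test_history_length_matches_epochs(self, tiny_run):
        _, cfg, res = tiny_run
        assert len(res.loss_history) == cfg.epochs

    def test_dale_training_preserves_signs(self):
        task = TaskConfig(n_psi=10, duration=0.05)
        cfg = TrainConfig(n_train=256, batch_size=64, epochs=2, n_hidden=4,
                          seed=3, dale_mode="balanced", n_test=128)
        res = train(task, cfg)
        assert np.all(res.params.w_ih * res.params.sign_mask_ih[:, None] >= 0)
        assert np.all(res.params.w_ho * res.params.sign_mask_ho[:, None] >= 0)


class TestTrainConfigValidation:
    def test_regularizer_thresholds_ordered(self):
        with pytest.raises(ValueError, match="r_plus"):
            TrainConfig(r_minus=200.0, r_plus=100.0)

    def test_batch_size_divides_n_train(self):
        with pytest.raises(ValueError, match="batch_size"):
            TrainConfig(n_train=1000, batch_size=128)


class TestEvaluate:
    def test_untrained_network_near_chance(self, rng):
        task = TaskConfig(n_psi=10)
        params = init_params(task, TrainConfig(n_hidden=4), rng)
        report = evaluate(params, task, 4096, rng)
        se = np.sqrt((1 / 12) * (11 / 12) / 4096)
        assert abs(report.accuracy - 1 / 12) < 4 * se
        # accuracy is the confusion diagonal mass
        assert report.confusion.trace() == round(report.accuracy * 4096)

    def test_confusion_rows_are_per_true_class_counts(self, rng):
        task = TaskConfig(n_psi=10)
        params = init_params(task, TrainConfig(n_hidden=4), rng)
        report = evaluate(params, task, 1024, rng)
        assert report.confusion.sum() == 1024
        assert np.all(report.confusion.sum(axis=1) >= 0)

    def test_oracle_classifier_mae(self, rng):
        """A perfect classifier's MAE equals the mean within-bin distance
        to the midpoint, ~ (pi/N_c)/4 (brute force over uniform IPDs)."""
        n_c = 12
        alphas = sample_ipds(200_000, rng)
        k = ipd_to_class(alphas, n_c)
        mae = np.abs(class_to_midpoint(k, n_c) - alphas).mean()
        assert mae == pytest.approx((np.pi / n_c) / 4, rel=0.02)
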