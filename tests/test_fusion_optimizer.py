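"""Tests for the alternating augmented-Lagrangian optimizer."""

import math

import numpy as np
import pytest

from dcef.fusion_core import (
    ClassifierWeights,
    FeatureBatch,
    FusionWeights,
    LabelBatch,
    cross_entropy,
    fused_loss,
)
from dcef.fusion_optimizer import (
    FitResult,
    LagrangeState,
    PerNetworkLossSummary,
    TrainConfig,
    fit,
    grad_classifier,
    project_simplex,
    update_multipliers,
    update_pi,
)
from dcef.synthetic_data import generate_feature_ensembles
from conftest import random_instance


def finite_difference_grad(fb, cw, lab, pi_k, h=1e-6):
    fd = np.zeros_like(cw.weights)
    for i in range(cw.weights.shape[0]):
        for j in range(cw.weights.shape[1]):
            wp, wm = cw.weights.copy(), cw.weights.copy()
            wp[i, j] += h
            wm[i, j] -= h
            fd[i, j] = (
                pi_k
                * (
                    cross_entropy(fb, ClassifierWeights(wp), lab)
                    - cross_entropy(fb, ClassifierWeights(wm), lab)
                )
                / (2 * h)
            )
    return fd


def grid_search_pi(ell, eta, xi, tau, step=1e-3):
    """Brute-force minimizer of the augmented objective over the simplex."""
    k = len(ell)
    grid = np.arange(0.0, 1.0 + step / 2, step)
    if k == 2:
        pis = np.column_stack([grid, 1 - grid])
    elif k == 3:
        a, b = np.meshgrid(grid, grid)
        keep = a + b <= 1 + 1e-12
        pis = np.column_stack([a[keep], b[keep], 1 - a[keep] - b[keep]])
    else:
        raise NotImplementedError
    resid = pis.sum(axis=1) - 1
    objective = (
        pis @ ell
        + eta * resid
        + pis @ xi
        + tau / 2 * (resid**2 + (pis**2).sum(axis=1))
    )
    return pis[np.argmin(objective)]


class TestGradClassifier:
    def test_zero_at_perfect_prediction(self):
        fb = FeatureBatch(np.array([[1.0, 0.0], [0.0, 1.0]]))
        cw = ClassifierWeights(np.array([[80.0, 0.0], [0.0, 80.0]]))
        lab = LabelBatch(np.array([0, 1]))
        g = grad_classifier(fb, cw, lab, pi_k=0.5)
        assert np.allclose(g, 0.0, atol=1e-20)

    def test_linear_in_pi(self, rng):
        fb, cw, lab = random_instance(rng, n=5, d=3)
        g1 = grad_classifier(fb, cw, lab, pi_k=0.25)
        g2 = grad_classifier(fb, cw, lab, pi_k=0.5)
        assert np.allclose(2 * g1, g2, rtol=1e-12)

    def test_matches_central_finite_differences(self):
        rng = np.random.default_rng(11)
        fb = FeatureBatch(rng.standard_normal((4, 3)))
        cw = ClassifierWeights(rng.standard_normal((3, 2)))
        lab = LabelBatch(rng.integers(0, 2, 4))
        g = grad_classifier(fb, cw, lab, pi_k=0.7)
        fd = finite_difference_grad(fb, cw, lab, 0.7)
        assert np.abs(g - fd).max() < 1e-5

    def test_invalid_pi_rejected(self, rng):
        fb, cw, lab = random_instance(rng)
        with pytest.raises(ValueError, match="pi_k"):
            grad_classifier(fb, cw, lab, pi_k=0.0)


class TestUpdatePi:
    def test_single_network_forced_to_one(self):
        out = update_pi(
            PerNetworkLossSummary(np.array([7.3])), LagrangeState.initial(1)
        )
        assert out.pi == pytest.approx([1.0])

    def test_equal_losses_give_uniform(self):
        for k in (2, 3, 5):
            out = update_pi(
                PerNetworkLossSummary(np.full(k, 0.8)),
                LagrangeState.initial(k),
            )
            assert np.allclose(out.pi, 1 / k, atol=1e-6)

    def test_matches_brute_force_simplex_search(self):
        # losses (0.2, 1.0), multipliers zero, tau=1: minimizer is (0.9, 0.1)
        state = LagrangeState.initial(2)
        mine = update_pi(PerNetworkLossSummary(np.array([0.2, 1.0])), state)
        oracle = grid_search_pi(np.array([0.2, 1.0]), 0.0, np.zeros(2), 1.0)
        assert np.abs(mine.pi - oracle).max() < 1e-2
        assert mine.pi == pytest.approx([0.9, 0.1], abs=1e-6)

    def test_higher_loss_never_gets_more_weight(self, rng):
        for _ in range(30):
            k = int(rng.integers(2, 6))
            ell = rng.uniform(0, 3, k)
            out = update_pi(
                PerNetworkLossSummary(ell), LagrangeState.initial(k)
            ).pi
            order = np.argsort(ell)
            assert np.all(np.diff(out[order]) <= 1e-12)

    def test_zero_tau_rejected(self):
        with pytest.raises(ValueError, match="tau"):
            LagrangeState(eta=0.0, xi=np.zeros(2), tau=0.0)

    def test_projection_lands_on_simplex(self, rng):
        for _ in range(200):
            v = rng.standard_normal(int(rng.integers(2, 7))) * 3
            pi = project_simplex(v)
            assert pi.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(pi > 0)


class TestUpdateMultipliers:
    def test_on_simplex_pi_leaves_eta_unchanged(self):
        state = LagrangeState.initial(2)
        new = update_multipliers(FusionWeights(np.array([0.5, 0.5])), state)
        assert new.eta == pytest.approx(state.eta)

    def test_tau_increase_equals_half_theta3_times_norms(self):
        # pi = (0.5, 0.5) with theta3 = 2: tau grows by ||pi||^2 = 0.5
        state = LagrangeState(
            eta=0.0, xi=np.zeros(2), tau=1.0, step_sizes=(0.1, 0.1, 2.0)
        )
        new = update_multipliers(FusionWeights(np.array([0.5, 0.5])), state)
        assert new.tau - state.tau == pytest.approx(0.5)

    def test_xi_update_adds_theta2_pi_elementwise(self):
        state = LagrangeState(
            eta=0.0, xi=np.zeros(2), tau=1.0, step_sizes=(0.1, 0.1, 0.1)
        )
        pi = FusionWeights(np.array([0.999999, 0.000001]))
        new = update_multipliers(pi, state)
        assert np.allclose(new.xi, 0.1 * pi.pi)

    def test_tau_strictly_increases(self, rng):
        state = LagrangeState.initial(3)
        for _ in range(10):
            pi = FusionWeights(project_simplex(rng.standard_normal(3)))
            new = update_multipliers(pi, state)
            assert new.tau > state.tau
            state = new


class TestFit:
    def test_frozen_weights_with_zero_learning_rate(self):
        batches, labels = generate_feature_ensembles(2, 12, seed=0)
        cfg = TrainConfig(lr=0.0, lr_min=0.0, epochs=1, t_max=1, batch_size=4)
        res = fit(batches, labels, cfg)
        for head in res.heads:
            assert np.all(head.weights == 0.0)
        # pi after one update equals update_pi on the epoch-0 losses
        ell = res.per_network_loss_history[1]
        expected = update_pi(
            PerNetworkLossSummary(ell), LagrangeState.initial(2)
        )
        assert np.allclose(res.fusion.pi, expected.pi)
        assert np.allclose(ell, math.log(2))  # zero heads predict uniformly

    def test_separable_features_reach_high_accuracy(self):
        batches, labels = generate_feature_ensembles(
            2, 60, informative=(1, 2), separability=4.0, seed=0
        )
        cfg = TrainConfig(epochs=30, t_max=30, batch_size=16, seed=0)
        res = fit(batches, labels, cfg)
        acc = np.mean(res.predict(batches) == labels.labels)
        assert acc >= 0.95

    def test_pure_noise_network_is_down_weighted(self):
        batches, labels = generate_feature_ensembles(
            3, 60, informative=(1, 2), separability=3.0, seed=5
        )
        cfg = TrainConfig(epochs=20, t_max=20, batch_size=16, seed=5)
        res = fit(batches, labels, cfg)
        assert res.fusion.pi[2] < 1 / 3

    def test_simplex_preserved_through_training(self):
        batches, labels = generate_feature_ensembles(3, 40, seed=1)
        res = fit(batches, labels, TrainConfig(epochs=10, t_max=10, batch_size=8))
        sums = res.pi_history.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert np.all(res.pi_history > 0)

    def test_tau_monotone_nondecreasing(self):
        batches, labels = generate_feature_ensembles(2, 30, seed=2)
        res = fit(batches, labels, TrainConfig(epochs=8, t_max=8, batch_size=8))
        assert res.lagrange.tau > 1.0  # grew from its initial value

    def test_adaptive_pi_no_worse_than_uniform_on_final_losses(self):
        batches, labels = generate_feature_ensembles(
            3, 50, informative=(1,), separability=3.0, seed=3
        )
        res = fit(batches, labels, TrainConfig(epochs=15, t_max=15, batch_size=16))
        nets = list(zip(batches, res.heads))
        adaptive = fused_loss(nets, labels, res.fusion, reduction="mean")
        uniform = fused_loss(
            nets, labels, FusionWeights.uniform(3), reduction="mean"
        )
        assert adaptive <= uniform + 1e-12

    def test_loss_history_trends_downward(self):
        batches, labels = generate_feature_ensembles(
            2, 60, informative=(1, 2), separability=3.0, seed=4
        )
        res = fit(batches, labels, TrainConfig(epochs=20, t_max=20, batch_size=16))
        hist = np.array(res.fused_loss_history)
        # non-increasing trend with slack: each epoch at most 5% above prior
        assert np.all(hist[1:] <= hist[:-1] + 0.05 * np.abs(hist[:-1]) + 1e-3)
        assert hist[-1] < hist[0]

    def test_identical_seeds_give_bit_identical_histories(self):
        batches, labels = generate_feature_ensembles(2, 40, seed=6)
        cfg = TrainConfig(epochs=6, t_max=6, batch_size=8, seed=9)
        res1 = fit(batches, labels, cfg)
        res2 = fit(batches, labels, cfg)
        assert res1.fused_loss_history == res2.fused_loss_history
        assert np.array_equal(res1.pi_history, res2.pi_history)

    def test_bundle_roundtrip(self, tmp_path):
        batches, labels = generate_feature_ensembles(2, 20, seed=7)
        res = fit(batches, labels, TrainConfig(epochs=3, t_max=3, batch_size=8))
        res.save(tmp_path / "bundle")
        loaded = FitResult.load(tmp_path / "bundle")
        assert np.allclose(loaded.fusion.pi, res.fusion.pi)
        for a, b in zip(loaded.heads, res.heads):
            assert np.array_equal(a.weights, b.weights)
        assert loaded.config == res.config
        assert np.array_equal(loaded.pi_history, res.pi_history)
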