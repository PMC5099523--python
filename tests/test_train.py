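"""Transfer function, gradients, normalized backprop, optimizers."""

import math

import numpy as np
import pytest

import spikegrad as sg
from spikegrad.network import SpikingNetwork, dense_layer
from spikegrad.train import (
    AdamState,
    TrainHyper,
    adam_step,
    apply_updates,
    backpropagate,
    epoch_decay,
    grad_input,
    grads_params,
    init_layer,
    output_error,
    transfer_function,
)
from spikegrad.wta import WTAConfig

from oracles import damped_fixed_point, full_activity_record


class TestInitLayer:
    def test_threshold_closed_form(self):
        _, vth = init_layer(300, 10, 3.0, seed=0)
        assert np.all(vth == pytest.approx(0.3))  # 3*sqrt(3/300)

    def test_unit_expected_row_energy(self, rng):
        W, _ = init_layer(50, 4000, 3.0, rng)
        row_sq = np.sum(W * W, axis=1)
        assert row_sq.mean() == pytest.approx(1.0, rel=0.02)

    def test_per_weight_variance(self, rng):
        M = 80
        W, _ = init_layer(M, 3000, 3.0, rng)
        assert W.var() == pytest.approx(1.0 / M, rel=0.05)

    def test_alpha_must_exceed_one(self):
        with pytest.raises(ValueError):
            init_layer(10, 5, 1.0, seed=0)


class TestTransferFunction:
    def test_uncoupled_is_drive_over_threshold(self):
        assert transfer_function([2.0], [0.5], kappa=0.0)[0] == pytest.approx(4.0)

    def test_two_neuron_wta_fixed_point(self):
        a = transfer_function([1.0, 0.5], [1.0, 1.0], kappa=-0.5, sigma=0.5)
        assert a == pytest.approx([0.93333333, 0.26666667])

    def test_linearity_without_coupling(self, rng):
        s = rng.uniform(0, 2, 5)
        vth = rng.uniform(0.5, 1.5, 5)
        a1 = transfer_function(s, vth, kappa=0.0)
        a2 = transfer_function(3.0 * s, vth, kappa=0.0)
        np.testing.assert_allclose(a2, 3.0 * a1, rtol=1e-12)

    def test_rectified_support_matches_damped_iteration(self, rng):
        """Silent units are excluded from the coupled system."""
        for _ in range(20):
            n = int(rng.integers(2, 8))
            s = rng.normal(0.5, 1.0, n)   # some drives negative
            vth = rng.uniform(0.5, 1.5, n)
            mu = float(rng.uniform(-0.6, 0.0))
            K = mu * (np.ones((n, n)) - np.eye(n))
            got = transfer_function(s, vth, kappa=mu, sigma=0.5)
            want = damped_fixed_point(s, vth, K, 0.5)
            np.testing.assert_allclose(got, want, rtol=1e-6, atol=1e-8)
            assert np.all(got >= 0)


class TestParameterGradients:
    def test_no_wta_threshold_gradient(self):
        a = transfer_function([2.0], [0.5], kappa=0.0)
        _, da_dvth, _ = grads_params(a, [2.0], [1.0], [0.5], kappa=0.0)
        assert da_dvth[0] == pytest.approx(-a[0] / 0.5)

    def test_inactive_synapse_gets_no_gradient(self):
        da_dw, _, _ = grads_params([1.0], [1.0], [0.0, 2.0], [1.0])
        assert da_dw[0, 0] == 0.0
        assert da_dw[0, 1] == pytest.approx(2.0)

    def test_finite_difference_per_neuron_relation(self, rng):
        """Eq-7-style first-order derivatives vs central differences of
        f_i = s_i/V_i + sigma*sum_j kappa_ij a_j with peers frozen."""
        sigma = 0.5
        for _ in range(100):
            n = int(rng.integers(2, 9))
            m = int(rng.integers(2, 17))
            x = rng.uniform(0, 2, m)
            W = rng.normal(0, 0.5, (n, m))
            vth = rng.uniform(0.4, 1.5, n)
            mu = float(rng.uniform(-0.8, 0.0))
            K = mu * (np.ones((n, n)) - np.eye(n))
            s = W @ x
            a = transfer_function(s, vth, kappa=mu, sigma=sigma)
            da_dw, da_dvth, da_dk = grads_params(a, s, x, vth, kappa=mu,
                                                 sigma=sigma)

            def f(i, s_i=None, vth_i=None, K_row=None):
                s_v = s[i] if s_i is None else s_i
                v_v = vth[i] if vth_i is None else vth_i
                row = K[i] if K_row is None else K_row
                return s_v / v_v + sigma * float(row @ a)

            support = np.flatnonzero(a > 0)
            if support.size == 0:
                continue
            i = int(support[int(rng.integers(0, support.size))])
            k = int(rng.integers(0, m))
            # d a_i / d w_ik  (through s_i = sum_k w_ik x_k)
            h = 1e-6
            fd_w = (f(i, s_i=s[i] + h * x[k]) - f(i, s_i=s[i] - h * x[k])) / (2 * h)
            assert fd_w == pytest.approx(da_dw[i, k], rel=1e-5, abs=1e-9)
            # d a_i / d V_th,i
            hv = 1e-6 * vth[i]
            fd_v = (f(i, vth_i=vth[i] + hv) - f(i, vth_i=vth[i] - hv)) / (2 * hv)
            assert fd_v == pytest.approx(da_dvth[i], rel=1e-5, abs=1e-8)
            # d a_i / d kappa_ih
            hcand = [j for j in range(n) if j != i]
            hh = hcand[int(rng.integers(0, len(hcand)))]
            Kp, Km = K[i].copy(), K[i].copy()
            Kp[hh] += 1e-6
            Km[hh] -= 1e-6
            fd_k = (f(i, K_row=Kp) - f(i, K_row=Km)) / 2e-6
            assert fd_k == pytest.approx(da_dk[i, hh], rel=1e-5, abs=1e-9)


class TestInputGradient:
    def test_reduces_to_weight_over_threshold(self, rng):
        W = rng.normal(size=(4, 6))
        vth = rng.uniform(0.5, 1.5, 4)
        A = grad_input(W, vth, mu=0.0)
        np.testing.assert_allclose(A, W / vth[:, None], rtol=1e-12)

    def test_single_neuron_any_mu(self, rng):
        W = rng.normal(size=(1, 5))
        for mu in (0.0, -0.3, -0.9):
            A = grad_input(W, [0.7], mu=mu)
            np.testing.assert_allclose(A, W / 0.7, rtol=1e-12)

    def test_uniform_closed_form_equals_matrix_inverse(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 9))
            m = int(rng.integers(2, 17))
            W = rng.normal(0, 1.0, (n, m))
            vth = rng.uniform(0.3, 2.0, n)
            mu = float(rng.uniform(-1.0, 0.0))
            sigma = float(rng.uniform(0.1, 1.0))
            if abs(1 + mu * sigma) < 1e-3:
                continue
            K = mu * (np.ones((n, n)) - np.eye(n))
            A_closed = grad_input(W, vth, mu=mu, sigma=sigma)
            A_inv = grad_input(W, vth, kappa=K, sigma=sigma)
            np.testing.assert_allclose(A_closed, A_inv, atol=1e-10)

    def test_matches_finite_difference_of_coupled_solve(self, rng):
        """The input gradient is exact for the full linear system."""
        checked = 0
        while checked < 25:
            n = int(rng.integers(2, 8))
            m = int(rng.integers(2, 10))
            W = np.abs(rng.normal(0.5, 0.3, (n, m)))
            vth = rng.uniform(0.5, 1.5, n)
            mu = float(rng.uniform(-0.6, 0.0))
            sigma = 0.5
            x = rng.uniform(0.5, 2.0, m)
            a = transfer_function(W @ x, vth, kappa=mu, sigma=sigma)
            if np.any(a <= 1e-9):
                continue  # clamped support: the linear gradient is one-sided
            checked += 1
            A = grad_input(W, vth, mu=mu, sigma=sigma)
            k = int(rng.integers(0, m))
            h = 1e-6
            xp, xm = x.copy(), x.copy()
            xp[k] += h
            xm[k] -= h
            fp = transfer_function(W @ xp, vth, kappa=mu, sigma=sigma)
            fm = transfer_function(W @ xm, vth, kappa=mu, sigma=sigma)
            np.testing.assert_allclose((fp - fm) / (2 * h), A[:, k],
                                       rtol=1e-5, atol=1e-8)

    def test_singularity_guard(self):
        with pytest.raises(np.linalg.LinAlgError):
            grad_input(np.ones((3, 2)), [1.0, 1.0, 1.0], mu=-1.0, sigma=1.0)


class TestOutputError:
    def test_max_normalization_and_nnze(self):
        e = output_error([3, 6, 0], [0, 1, 0])
        np.testing.assert_allclose(e, [0.5, 0.0, 0.0])

    def test_perfect_output_zero_error(self):
        e = output_error([0, 7, 0], [0, 1, 0])
        assert np.all(e == 0)

    def test_all_silent_network(self):
        e = output_error([0, 0, 0], [0, 1, 0])
        np.testing.assert_allclose(e, [0, -1.0, 0])


class TestBackpropagation:
    def test_identity_chain_preserves_delta(self):
        net = SpikingNetwork([dense_layer(1, 1), dense_layer(1, 1)],
                             tau_mp=0.02)
        for l in range(2):
            net.weights[l][:] = 1.0
            net.vth[l][:] = 1.0
        rec = full_activity_record(net)
        grads = backpropagate(rec, np.array([0.3]), net)
        assert grads[0].delta[0] == pytest.approx(0.3)

    def test_error_energy_constant_at_init(self, rng):
        """E[sum delta^2] stays ~1 across layers (quick; deeper in acceptance)."""
        specs = [dense_layer(300, 200, 3.0), dense_layer(200, 100, 4.0),
                 dense_layer(100, 50, 3.0)]
        net = SpikingNetwork(specs, tau_mp=0.02)
        E = np.zeros(3)
        n_draws = 200
        for _ in range(n_draws):
            net.initialize(rng)
            e = rng.normal(size=50)
            e /= np.linalg.norm(e)
            grads = backpropagate(full_activity_record(net), e, net)
            for l in range(3):
                E[l] += np.sum(grads[l].delta ** 2)
        E /= n_draws
        np.testing.assert_allclose(E, 1.0, rtol=0.10)

    def test_inactive_neurons_blocked(self, rng):
        net = SpikingNetwork([dense_layer(4, 3), dense_layer(3, 2)])
        net.initialize(rng)
        rec = full_activity_record(net)
        rec.layers[0].active_out[1] = False
        rec.layers[0].a[1] = 0.0
        grads = backpropagate(rec, np.array([0.5, -0.5]), net)
        assert grads[0].delta[1] == 0.0
        assert np.all(grads[0].dW.reshape(3, 4)[1] == 0.0)

    def test_update_scaling_collapse(self, rng):
        """With N = m (all inputs active) and no WTA, gW = delta x exactly."""
        net = SpikingNetwork([dense_layer(4, 4)])
        net.initialize(rng)
        rec = full_activity_record(net)
        e = np.array([0.5, -0.25, 0.1, 0.0])
        grads = backpropagate(rec, e, net)
        np.testing.assert_allclose(grads[0].dW.reshape(4, 4),
                                   np.outer(e, rec.layers[0].x), rtol=1e-12)
        # sqrt(N/m) amplification when only one input is active
        rec.layers[0].active_in[1:] = False
        grads2 = backpropagate(rec, e, net)
        np.testing.assert_allclose(grads2[0].dW.reshape(4, 4),
                                   2.0 * np.outer(e, rec.layers[0].x),
                                   rtol=1e-12)  # sqrt(4/1) = 2

    def test_threshold_update_direction(self, rng):
        """Under-responding target neuron gets its threshold lowered."""
        net = SpikingNetwork([dense_layer(4, 2)])
        net.initialize(rng)
        rec = full_activity_record(net)
        e = np.array([-0.5, 0.0])   # target neuron 0 under-responds
        grads = backpropagate(rec, e, net)
        vth_before = net.vth[0].copy()
        apply_updates(net, grads, TrainHyper(optimizer="sgd", eta_w=0.01))
        assert net.vth[0][0] < vth_before[0]

    def test_duplicate_sample_doubles_sgd_update(self, rng):
        net = SpikingNetwork([dense_layer(4, 2)])
        net.initialize(rng)
        rec = full_activity_record(net)
        e = np.array([0.4, -0.1])
        hyper = TrainHyper(optimizer="sgd", eta_w=0.01)
        g1 = backpropagate(rec, e, net)
        g2 = backpropagate(rec, e, net)
        np.testing.assert_allclose(g1[0].dW + g2[0].dW, 2 * g1[0].dW,
                                   rtol=1e-15)

    def test_sgd_eta_ratio(self):
        h = TrainHyper(optimizer="sgd", eta_w=0.004)
        assert h.resolved_eta_th() == pytest.approx(0.1 * 0.004)
        h2 = TrainHyper(optimizer="adam", eta_w=0.004)
        assert h2.resolved_eta_th() == pytest.approx(0.004)


class TestAdam:
    def test_first_step_magnitude(self):
        st = AdamState.like(np.zeros(1))
        d, _ = adam_step(np.array([0.37]), st, 1, eta=0.01)
        assert abs(d[0]) == pytest.approx(0.01, rel=1e-6)
        assert np.sign(d[0]) == -1

    def test_zero_gradient_freezes(self):
        st = AdamState.like(np.zeros(2))
        for t in range(1, 5):
            d, st = adam_step(np.zeros(2), st, t, eta=0.01)
            assert np.all(d == 0)

    def test_reference_recursion(self):
        """Match a hand-computed 10-step scalar ADAM trace."""
        b1, b2, eps, eta = 0.9, 0.999, 1e-8, 0.1
        gs = [0.5, -0.2, 0.3, 0.1, -0.4, 0.25, 0.0, -0.1, 0.2, 0.05]
        m = v = 0.0
        theta_ref = 0.0
        st = AdamState.like(np.zeros(1))
        theta = 0.0
        for t, g in enumerate(gs, start=1):
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            theta_ref -= eta * (m / (1 - b1 ** t)) / (
                math.sqrt(v / (1 - b2 ** t)) + eps)
            d, st = adam_step(np.array([g]), st, t, b1, b2, eps, eta)
            theta += d[0]
        assert theta == pytest.approx(theta_ref, rel=1e-12)


class TestSchedules:
    def test_epoch_decay_closed_form(self):
        v = 1.0
        for _ in range(35):
            v = epoch_decay(v)
        assert v == pytest.approx(math.exp(-1), rel=1e-12)

    def test_zero_epochs_unchanged(self):
        assert epoch_decay(0.123, 0) == 0.123

    def test_same_schedule_for_all_decayed_quantities(self):
        net = SpikingNetwork([dense_layer(4, 2)])
        net.initialize(np.random.default_rng(0))
        tr = sg.Trainer(net, TrainHyper(eta_w=0.004, rho=2e-4))
        r0, e0 = tr.rho, tr.eta_w
        tr.end_epoch()
        assert tr.rho / r0 == pytest.approx(tr.eta_w / e0)
        assert tr.eta_w / e0 == pytest.approx(math.exp(-1 / 35))
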