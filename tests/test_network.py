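"""Closed-loop network semantics: currents, decoding, the FOLLOW update,
kernel/numpy equivalence, and feedback behaviour."""

import numpy as np
import pytest

import follownet as fn
from follownet.config import SYSTEM_TABLE
from follownet.experiments import _protocol_input, build_network
from follownet.reference_systems import integrate_reference, make_reference
from follownet.signals import filter_series


def run_numpy(net, u, xref, dt, cfg, noise=None):
    st = net.init_state()
    xhats = []
    for t in range(u.shape[0]):
        st, xhat, eps, _, _ = net.step(
            st, u[t], xref[t], dt, cfg,
            noise=None if noise is None else noise[t])
        xhats.append(xhat)
    return st, np.array(xhats)


class TestCurrents:
    def test_command_currents_affine(self, tiny_linear_net):
        net, _ = tiny_linear_net
        b = net.cmd_ensemble.biases
        np.testing.assert_allclose(net.command_currents(np.zeros(2)), b)
        j1 = net.command_currents(np.array([0.1, 0.0])) - b
        j2 = net.command_currents(np.array([0.0, -0.2])) - b
        j12 = net.command_currents(np.array([0.1, -0.2])) - b
        np.testing.assert_allclose(j12, j1 + j2, atol=1e-12)

    def test_command_projection_at_radius(self):
        """A command on the R1-sphere aligned with a neuron's encoder drives a
        projection term equal to that neuron's gain."""
        ens = fn.sample_tuning(30, 2, 0.2, "fixed_gain", np.random.default_rng(0))
        net, _ = build_network("linear", n_neurons=30, seed=0)
        net = fn.FollowNetwork(ens, net.rec_ensemble, fn.WeightSet.zeros(
            ens, net.rec_ensemble, net.weights.decoders))
        i = 7
        u = ens.encoders[i] / np.linalg.norm(ens.encoders[i]) * 0.2
        J = net.command_currents(u)
        assert J[i] - ens.biases[i] == pytest.approx(ens.gains[i], rel=1e-9)

    def test_recurrent_currents_zero_weights(self, tiny_linear_net):
        net, _ = tiny_linear_net
        st = net.init_state()
        np.testing.assert_allclose(
            net.recurrent_currents(st, feedback_on=True),
            net.rec_ensemble.biases)

    def test_static_error_feedback_dc_gain(self, tiny_linear_net):
        """Zero weights, feedback on, constant error: current offset converges
        to k * e_i . eps (unit DC gain of the kappa filter)."""
        net, _ = tiny_linear_net
        st = net.init_state()
        eps = np.array([0.3, -0.1])
        for _ in range(600):
            st.err_traces *= np.exp(-1e-3 / net.tau_s)
            st.err_traces += eps * (1 - np.exp(-1e-3 / net.tau_s))
        J = net.recurrent_currents(st, feedback_on=True)
        expected = (net.rec_ensemble.biases
                    + net.weights.fb_gain * net.weights.fb_encoders @ eps)
        np.testing.assert_allclose(J, expected, rtol=1e-9)
        # feedback off: error term absent
        np.testing.assert_allclose(
            net.recurrent_currents(st, feedback_on=False),
            net.rec_ensemble.biases)


class TestDecodeAndUpdate:
    def test_decode_zero_traces(self, tiny_linear_net):
        net, _ = tiny_linear_net
        np.testing.assert_array_equal(
            net.decode(np.zeros(net.rec_ensemble.n_neurons)), 0.0)

    def test_decode_single_impulse_response(self, tiny_linear_net):
        """One spike in neuron j: output is d_aj * exp(-t/tau_s)/tau_s."""
        net, _ = tiny_linear_net
        traces = np.zeros(net.rec_ensemble.n_neurons)
        traces[3] = 1.0 / net.tau_s
        out0 = net.decode(traces)
        np.testing.assert_allclose(out0, net.weights.decoders[:, 3] / net.tau_s)
        decay = np.exp(-0.010 / net.tau_s)
        np.testing.assert_allclose(net.decode(traces * decay), out0 * decay)

    def test_follow_update_values_and_structure(self, tiny_linear_net):
        """Rank-1 row structure: increments of neuron i share the factor
        learn_err_trace_i; magnitude is eta*dt/n_pre * trace product."""
        net, _ = tiny_linear_net
        n = net.rec_ensemble.n_neurons
        ltr = np.linspace(0.1, 1.0, n)
        ctr = np.linspace(-0.5, 0.5, n)
        rtr = np.linspace(0.0, 2.0, n)
        d_ff, d_rec = net.follow_update(ltr, ctr, rtr, eta=2e-4, dt=1e-3)
        assert d_ff[5, 8] == pytest.approx(2e-4 * 1e-3 / n * ltr[5] * ctr[8])
        # every row is proportional to the pre-trace vector
        for i in (0, 13, n - 1):
            np.testing.assert_allclose(d_rec[i], 2e-4 * 1e-3 / n * ltr[i] * rtr,
                                       atol=1e-30)

    def test_zero_error_history_no_increments(self, tiny_linear_net):
        net, _ = tiny_linear_net
        d_ff, d_rec = net.follow_update(
            np.zeros(net.rec_ensemble.n_neurons),
            np.ones(net.cmd_ensemble.n_neurons),
            np.ones(net.rec_ensemble.n_neurons), eta=2e-4, dt=1e-3)
        assert np.all(d_ff == 0) and np.all(d_rec == 0)


class TestClosedLoop:
    def _series(self, net, rng_in, duration=0.5, dt=1e-3):
        table = SYSTEM_TABLE["linear"]
        spec = make_reference("linear")
        u = _protocol_input("linear", table, duration, dt, rng_in, 2)
        xref = filter_series(integrate_reference(spec, u, dt), net.tau_s, dt)
        return u, xref

    def test_zero_weights_feedback_off_output_stays_near_zero(self, tiny_linear_net):
        """Tabula rasa, no feedback: neurons fire at their bias-driven rates,
        which the decoders map to approximately zero, so the output stays flat
        near zero while the reference oscillates."""
        net, (rng_in, _) = build_network("linear", n_neurons=300, seed=11)
        u, xref = self._series(net, rng_in, duration=2.0)
        cfg = fn.LearnConfig(feedback_on=False, plasticity_on=False, eta=0.0)
        rec = net.run_phase(net.init_state(), u, xref, 1e-3, cfg)
        out_rms = np.linalg.norm(rec.xhat, axis=1).mean()
        ref_rms = np.linalg.norm(xref, axis=1).mean()
        assert out_rms < 0.25 * ref_rms
        # and the error is essentially the reference itself
        np.testing.assert_allclose(rec.err, xref[::10] - rec.xhat, atol=1e-12)

    def test_eta_zero_weights_bit_identical(self, tiny_linear_net):
        net, rng_in = tiny_linear_net
        u, xref = self._series(net, rng_in)
        w_before = net.weights.w_rec.copy()
        cfg = fn.LearnConfig(feedback_on=True, plasticity_on=True, eta=0.0)
        net.run_phase(net.init_state(), u, xref, 1e-3, cfg)
        np.testing.assert_array_equal(net.weights.w_rec, w_before)

    def test_kernel_matches_numpy_step(self):
        """The numba kernel and the reference step() produce the same outputs,
        traces and learned weights on a short closed-loop run."""
        dt = 1e-3
        net_a, (rng_in, _) = build_network("linear", n_neurons=50, seed=3)
        net_b, _ = build_network("linear", n_neurons=50, seed=3)
        table = SYSTEM_TABLE["linear"]
        spec = make_reference("linear")
        u = _protocol_input("linear", table, 0.4, dt, rng_in, 2)
        xref = filter_series(integrate_reference(spec, u, dt), net_a.tau_s, dt)
        cfg = fn.LearnConfig(eta=2e-3, feedback_on=True, plasticity_on=True)

        st_b, xhat_b = run_numpy(net_b, u, xref, dt, cfg)
        rec = net_a.run_phase(net_a.init_state(), u, xref, dt, cfg,
                              record_every=1)
        np.testing.assert_allclose(rec.xhat, xhat_b, atol=1e-9)
        np.testing.assert_allclose(net_a.weights.w_rec, net_b.weights.w_rec,
                                   atol=1e-12)
        np.testing.assert_allclose(net_a.weights.w_ff, net_b.weights.w_ff,
                                   atol=1e-12)

    def test_sparsity_masks_conserved(self):
        """Masked synapses stay exactly zero through learning."""
        dt = 1e-3
        net, (rng_in, _) = build_network("linear", n_neurons=60, seed=5,
                                         connectivity=0.3)
        table = SYSTEM_TABLE["linear"]
        spec = make_reference("linear")
        u = _protocol_input("linear", table, 1.0, dt, rng_in, 2)
        xref = filter_series(integrate_reference(spec, u, dt), net.tau_s, dt)
        cfg = fn.LearnConfig(eta=0.1, feedback_on=True, plasticity_on=True)
        net.run_phase(net.init_state(), u, xref, dt, cfg)
        w = net.weights
        assert np.all(w.w_rec[w.mask_rec == 0.0] == 0.0)
        assert np.all(w.w_ff[w.mask_ff == 0.0] == 0.0)
        assert np.any(w.w_rec[w.mask_rec == 1.0] != 0.0)

    def test_run_phase_deterministic_and_empty(self, tiny_linear_net):
        net, rng_in = tiny_linear_net
        u, xref = self._series(net, rng_in)
        cfg = fn.LearnConfig(feedback_on=True, plasticity_on=False, eta=0.0)
        r1 = net.run_phase(net.init_state(), u, xref, 1e-3, cfg)
        r2 = net.run_phase(net.init_state(), u, xref, 1e-3, cfg)
        np.testing.assert_array_equal(r1.xhat, r2.xhat)
        r0 = net.run_phase(net.init_state(), u[:0], xref[:0], 1e-3, cfg)
        assert r0.xhat.shape == (0, 2) and r0.duration == 0.0

    def test_recorder_decimation_count(self, tiny_linear_net):
        net, rng_in = tiny_linear_net
        u, xref = self._series(net, rng_in, duration=0.2)
        cfg = fn.LearnConfig(feedback_on=False, plasticity_on=False, eta=0.0)
        rec = net.run_phase(net.init_state(), u, xref, 1e-3, cfg,
                            record_every=10)
        assert rec.xhat.shape[0] == 20

    def test_spike_rate_bound(self, tiny_linear_net):
        """No neuron exceeds the refractory limit of 500 Hz."""
        net, rng_in = tiny_linear_net
        u, xref = self._series(net, rng_in, duration=1.0)
        cfg = fn.LearnConfig(feedback_on=True, plasticity_on=False, eta=0.0)
        rec = net.run_phase(net.init_state(), u, xref, 1e-3, cfg)
        assert rec.spike_counts_rec.max() <= 500
        assert rec.spike_counts_cmd.max() <= 500

    def test_decoder_perturbation_applied_once(self):
        net_a, _ = build_network("linear", n_neurons=40, seed=9)
        net_b, _ = build_network("linear", n_neurons=40, seed=9,
                                 decoder_perturb=(0.5, 0.1))
        nz = net_a.weights.decoders != 0.0
        ratio = net_b.weights.decoders[nz] / net_a.weights.decoders[nz]
        assert np.all(ratio >= 1 - 0.5 + 0.1 - 1e-9)
        assert np.all(ratio < 1 + 0.5 + 0.1 + 1e-9)
        # feedback encoders untouched
        np.testing.assert_array_equal(net_b.weights.fb_encoders,
                                      net_a.weights.fb_encoders)

    def test_error_noise_enters_error_node(self, tiny_linear_net):
        net, rng_in = tiny_linear_net
        u, xref = self._series(net, rng_in, duration=0.3)
        cfg = fn.LearnConfig(feedback_on=False, plasticity_on=False, eta=0.0,
                             error_noise_sigma=0.5)
        rec = net.run_phase(net.init_state(), u, xref, 1e-3, cfg,
                            record_every=1,
                            noise_rng=np.random.default_rng(0))
        # with zero weights and feedback off, err = xref + noise
        resid = rec.err - xref
        assert resid.std() == pytest.approx(0.5, rel=0.15)


class TestFeedbackClamp:
    def test_relative_error_near_one_over_k_plus_one(self):
        """Zero plastic weights, k=10: the loop tracks the reference with
        relative error within [0.5, 2] / (k+1) after the transient."""
        dt = 1e-3
        net, (rng_in, _) = build_network("linear", n_neurons=400, seed=1)
        table = SYSTEM_TABLE["linear"]
        spec = make_reference("linear")
        u = _protocol_input("linear", table, 6.0, dt, rng_in, 2)
        xref = filter_series(integrate_reference(spec, u, dt), net.tau_s, dt)
        cfg = fn.LearnConfig(eta=0.0, feedback_on=True, plasticity_on=False)
        rec = net.run_phase(net.init_state(), u, xref, dt, cfg, record_every=1)
        rel = (np.linalg.norm(rec.err[1000:], axis=1).mean()
               / np.linalg.norm(xref[1000:], axis=1).mean())
        assert 0.5 / 11 <= rel <= 2.0 / 11
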