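"""Experiment protocols and their metrics."""

import numpy as np
import pytest

import follownet as fn


class TestMseBlocks:
    def test_zero_error(self):
        blocks = fn.mse_blocks(np.zeros((800, 2)), dt=0.01, block=4.0)
        assert np.all(blocks == 0.0)
        assert blocks.shape == (2,)

    def test_constant_error_value(self):
        # eps = (0.1, 0) constant, Nd=2 -> (0.01 + 0)/2 = 0.005 per block
        err = np.tile([0.1, 0.0], (400, 1))
        blocks = fn.mse_blocks(err, dt=0.01, block=4.0)
        np.testing.assert_allclose(blocks, 0.005)

    def test_dimension_permutation_invariant(self):
        rng = np.random.default_rng(0)
        err = rng.standard_normal((1200, 3))
        b1 = fn.mse_blocks(err, dt=0.01)
        b2 = fn.mse_blocks(err[:, [2, 0, 1]], dt=0.01)
        np.testing.assert_allclose(b1, b2)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            fn.mse_blocks(np.zeros((10, 2)), dt=0.01, block=4.0)


class TestWeightR2:
    def test_identical_matrices(self):
        w = np.random.default_rng(0).standard_normal((20, 20))
        assert fn.weight_r2(w, w) == 1.0

    def test_zero_learned_nonzero_reference(self):
        w = np.random.default_rng(1).standard_normal((30, 30))
        expected = 1 - np.sum(w**2) / np.sum((w - w.mean())**2)
        assert fn.weight_r2(np.zeros_like(w), w) == pytest.approx(expected)
        assert fn.weight_r2(np.zeros_like(w), w) <= 0.0

    def test_independent_random_matrices_score_low(self):
        rng = np.random.default_rng(2)
        scores = [fn.weight_r2(rng.standard_normal((40, 40)),
                               rng.standard_normal((40, 40)))
                  for _ in range(20)]
        assert np.mean(scores) < 0.05

    def test_zero_variance_reference_rejected(self):
        with pytest.raises(ValueError):
            fn.weight_r2(np.ones((3, 3)), np.ones((3, 3)))


class TestTentMap:
    def test_sine_gives_single_point(self):
        t = np.arange(0, 50, 1e-2)
        pairs = fn.tent_map(np.sin(t))
        assert len(pairs) > 3
        np.testing.assert_allclose(pairs[:, 0], pairs[0, 0], atol=1e-4)
        np.testing.assert_allclose(pairs[:, 1], pairs[:, 0], atol=1e-4)

    def test_monotone_series_empty(self):
        assert fn.tent_map(np.arange(100.0)).shape == (0, 2)
        assert fn.tent_map(np.array([1.0, 2.0])).shape == (0, 2)

    def test_lorenz_reference_is_unimodal_tent(self):
        """Successive maxima of the Lorenz third coordinate trace a
        single-humped map: rising then falling, with an interior peak."""
        spec = fn.make_reference("lorenz")
        u = fn.lorenz_kick(3.0, 60.0, 1e-3, np.random.default_rng(0))
        x = fn.integrate_reference(spec, u, 1e-3)
        pairs = fn.tent_map(x[5000:, 2])
        assert len(pairs) > 30
        # coarse unimodality: binned means rise then fall exactly once
        order = np.argsort(pairs[:, 0])
        sorted_pairs = pairs[order]
        nbins = 6
        binned = np.array_split(sorted_pairs, nbins)
        means = np.array([b[:, 1].mean() for b in binned])
        direction = np.sign(np.diff(means))
        switches = np.sum(np.diff(direction) != 0)
        assert means.argmax() not in (0,)      # interior (or right-edge) peak
        assert switches <= 1                    # one rise-fall change at most


class TestRateHistogram:
    def test_empty_raster(self):
        out = fn.rate_histogram(np.zeros((1000, 20), np.uint8), dt=1e-3)
        assert out["mean_rate"] == 0.0
        assert np.all(out["rates"] == 0.0)

    def test_constructed_counts(self):
        raster = np.zeros((1000, 3), np.uint8)
        raster[::100, 0] = 1          # 10 spikes in 1 s window
        raster[::10, 1] = 1           # 100 spikes
        out = fn.rate_histogram(raster, dt=1e-3, t0=0.0, window=1.0)
        np.testing.assert_allclose(out["rates"], [10.0, 100.0, 0.0])
        assert out["mean_rate"] == pytest.approx(110.0 / 3)

    def test_window_selection(self):
        raster = np.zeros((2000, 1), np.uint8)
        raster[1500:1750:10, 0] = 1   # 25 spikes in the window [1.5, 1.75)
        out = fn.rate_histogram(raster, dt=1e-3, t0=1.5, window=0.25)
        assert out["rates"][0] == pytest.approx(100.0)


class TestProtocols:
    def test_no_learning_keeps_output_near_zero(self):
        """With zero learning time the network never sees feedback, so the
        open-loop test output stays at the bias-decode level (near zero)."""
        res = fn.learning_protocol("linear", n_neurons=150, t_pre=1.0,
                                   t_learn=0.0, t_test=3.0, seed=2,
                                   keep_network=False)
        out = np.linalg.norm(res.phases["test"].xhat, axis=1).mean()
        ref = np.linalg.norm(res.xref["test"], axis=1).mean()
        assert out < 0.3 * ref
        assert res.block_mse.size == 0

    def test_clamping_during_learning(self):
        """During the learning phase the error is much smaller than the
        reference (high-gain negative feedback)."""
        res = fn.learning_protocol("linear", n_neurons=300, t_pre=1.0,
                                   t_learn=12.0, t_test=0.0, seed=3,
                                   keep_network=False, record_every=1)
        err = np.linalg.norm(res.phases["learn"].err[2000:], axis=1).mean()
        ref = np.linalg.norm(res.xref["learn"][2000:], axis=1).mean()
        assert err < 0.35 * ref

    def test_connectivity_one_reproduces_base_run(self):
        """connectivity=1 and (chi, xi) = (0, 0) change nothing (same seeds)."""
        base = fn.learning_protocol("linear", n_neurons=80, t_pre=0.5,
                                    t_learn=4.0, t_test=0.0, seed=4,
                                    keep_network=False, record_every=1)
        same = fn.learning_protocol("linear", n_neurons=80, t_pre=0.5,
                                    t_learn=4.0, t_test=0.0, seed=4,
                                    connectivity=1.0, decoder_perturb=(0.0, 0.0),
                                    keep_network=False, record_every=1)
        np.testing.assert_array_equal(base.phases["learn"].err,
                                      same.phases["learn"].err)

    def test_delay_wiring(self):
        """A sensory delay shifts the reference at the error node; with
        compensation the command path is shifted identically (the reference
        system itself still sees the undelayed command)."""
        kw = dict(n_neurons=60, t_pre=0.0, t_learn=2.0, t_test=0.0, seed=5,
                  keep_network=False, record_every=1)
        base = fn.learning_protocol("linear", **kw)
        delayed = fn.learning_protocol("linear", reference_delay=0.02, **kw)
        comp = fn.learning_protocol("linear", reference_delay=0.02,
                                    compensate_command_delay=True, **kw)
        shift = 20
        # same seed -> same raw input; reference delayed by exactly 20 ticks
        np.testing.assert_array_equal(delayed.xref["learn"][shift:],
                                      base.xref["learn"][:-shift])
        np.testing.assert_array_equal(delayed.xref["learn"][:shift], 0.0)
        # uncompensated: command path unshifted; compensated: shifted too
        np.testing.assert_array_equal(delayed.u["learn"], base.u["learn"])
        np.testing.assert_array_equal(comp.u["learn"][shift:],
                                      base.u["learn"][:-shift])

    def test_readout_relearn_shuffled_worse(self):
        """Perceptron relearning of the readout succeeds for the learned
        weight matrix but degrades when its entries are shuffled."""
        res = fn.learning_protocol("linear", n_neurons=200, t_pre=0.0,
                                   t_learn=60.0, t_test=0.0, seed=6)
        net = res.network
        out_true = fn.readout_relearn(net, "linear", duration=30.0, seed=6,
                                      eta_r=1e-4)
        out_shuf = fn.readout_relearn(net, "linear", duration=30.0, seed=6,
                                      eta_r=1e-4, shuffle=True)
        # learning reduces the output error over time in the true condition
        n = out_true["error_curve"].size
        assert out_true["error_curve"][-n // 5:].mean() < \
            out_true["error_curve"][: n // 5].mean()
        assert out_true["final_error"] < out_shuf["final_error"]

    def test_eta_r_zero_keeps_readout_zero(self):
        res = fn.learning_protocol("linear", n_neurons=80, t_pre=0.0,
                                   t_learn=4.0, t_test=0.0, seed=7)
        out = fn.readout_relearn(res.network, "linear", duration=2.0, seed=7,
                                 eta_r=0.0)
        assert np.all(out["readout"] == 0.0)
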