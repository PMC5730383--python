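"""The two-layer spiking network with error feedback and FOLLOW plasticity.

Architecture: a command-representation layer of LIF neurons encodes the motor
command; its filtered spike trains reach a recurrent layer through plastic
feedforward weights; the recurrent layer carries plastic lateral weights, a
fixed linear readout decoding the predicted state ``x_hat``, and fixed random
error-feedback encoders of gain ``k`` injecting the (filtered) output error
``eps = x_ref - x_hat`` back into every neuron.  While feedback is on, both
plastic matrices follow the FOLLOW rule

    dw_ij/dt = eta * (I_eps_i * kappa_eps) * (S_j * kappa),

the product of the slow-filtered projected error current in the postsynaptic
neuron and the fast-filtered presynaptic spike trace.

Two execution paths exist: :meth:`FollowNetwork.step` is the plain numpy
reference for one tick (used in tests and tiny runs), and
:meth:`FollowNetwork.run_phase` drives the numba kernel for long simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import run_phase_kernel
from .lif import DEFAULT_PARAMS, LIFState, NeuronParams, TuningEnsemble, lif_step

__all__ = ["WeightSet", "NetworkState", "LearnConfig", "PhaseRecord", "FollowNetwork"]


@dataclass
class WeightSet:
    """Plastic matrices plus the fixed decoders and error-feedback encoders.

    ``fb_encoders`` are the weighted encoders ``e_ia = nu_i * e~_ia`` of the
    recurrent ensemble; the feedback current is ``k * e_ia * eps_a``.  Optional
    binary masks freeze absent synapses at exactly zero (sparse connectivity).
    """

    w_ff: np.ndarray
    w_rec: np.ndarray
    decoders: np.ndarray
    fb_encoders: np.ndarray
    fb_gain: float = 10.0
    mask_ff: np.ndarray | None = None
    mask_rec: np.ndarray | None = None

    @classmethod
    def zeros(
        cls,
        cmd_ensemble: TuningEnsemble,
        rec_ensemble: TuningEnsemble,
        decoders: np.ndarray,
        fb_gain: float = 10.0,
        connectivity: float = 1.0,
        decoder_perturb: tuple[float, float] | None = None,
        rng: np.random.Generator | None = None,
    ) -> "WeightSet":
        """Tabula-rasa weights (all-zero plastic matrices).

        ``connectivity`` < 1 draws Bernoulli masks for both plastic matrices.
        ``decoder_perturb = (chi, xi)`` multiplies every decoder entry once by
        ``1 + Uniform(-chi + xi, chi + xi)`` (the feedback encoders are left
        untouched).
        """
        n_rec = rec_ensemble.n_neurons
        n_cmd = cmd_ensemble.n_neurons
        decoders = np.array(decoders, dtype=float, copy=True)
        mask_ff = mask_rec = None
        if connectivity < 1.0:
            if not 0.0 < connectivity:
                raise ValueError("connectivity must be in (0, 1]")
            if rng is None:
                raise ValueError("connectivity < 1 requires an rng")
            mask_ff = (rng.random((n_rec, n_cmd)) < connectivity).astype(float)
            mask_rec = (rng.random((n_rec, n_rec)) < connectivity).astype(float)
        if decoder_perturb is not None:
            chi, xi = decoder_perturb
            if chi != 0.0 or xi != 0.0:
                if rng is None:
                    raise ValueError("decoder_perturb requires an rng")
                gamma = rng.uniform(-chi + xi, chi + xi, size=decoders.shape)
                decoders *= 1.0 + gamma
        return cls(
            w_ff=np.zeros((n_rec, n_cmd)),
            w_rec=np.zeros((n_rec, n_rec)),
            decoders=decoders,
            fb_encoders=rec_ensemble.weighted_encoders(),
            fb_gain=float(fb_gain),
            mask_ff=mask_ff,
            mask_rec=mask_rec,
        )

    def copy(self) -> "WeightSet":
        return WeightSet(
            self.w_ff.copy(), self.w_rec.copy(), self.decoders.copy(),
            self.fb_encoders.copy(), self.fb_gain,
            None if self.mask_ff is None else self.mask_ff.copy(),
            None if self.mask_rec is None else self.mask_rec.copy(),
        )

    def to_npz(self, path) -> None:
        data = dict(w_ff=self.w_ff, w_rec=self.w_rec, decoders=self.decoders,
                    fb_encoders=self.fb_encoders, fb_gain=self.fb_gain)
        if self.mask_ff is not None:
            data["mask_ff"] = self.mask_ff
        if self.mask_rec is not None:
            data["mask_rec"] = self.mask_rec
        np.savez(path, **data)

    @classmethod
    def from_npz(cls, path) -> "WeightSet":
        with np.load(path, allow_pickle=False) as f:
            return cls(
                w_ff=f["w_ff"], w_rec=f["w_rec"], decoders=f["decoders"],
                fb_encoders=f["fb_encoders"], fb_gain=float(f["fb_gain"]),
                mask_ff=f["mask_ff"] if "mask_ff" in f else None,
                mask_rec=f["mask_rec"] if "mask_rec" in f else None,
            )


@dataclass
class LearnConfig:
    """Switches and constants of one protocol phase.

    eta_schedule : optional list of ``(t_phase, factor)`` pairs; from phase
        time ``t_phase`` onward the rate is ``eta * factor`` (the Fig.-2-style
        x20 boost after 1,000 s is ``[(1000.0, 20.0)]``).
    reference_delay : sensory delay applied to the reference signal before the
        error node; ``compensate_command_delay`` delays the network's command
        input by the same amount (the reference system still sees the
        undelayed command).
    """

    eta: float = 2e-4
    eta_schedule: list[tuple[float, float]] | None = None
    tau_eps: float = 0.200
    feedback_on: bool = True
    plasticity_on: bool = True
    error_noise_sigma: float = 0.0
    reference_delay: float = 0.0
    compensate_command_delay: bool = False

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be non-negative")
        if not self.tau_eps > 0:
            raise ValueError("tau_eps must be positive")
        if self.reference_delay < 0:
            raise ValueError("reference_delay must be non-negative")

    def eta_series(self, n_steps: int, dt: float) -> np.ndarray:
        """Per-tick eta*dt values implementing the schedule (0 if frozen)."""
        if not self.plasticity_on or self.eta == 0.0:
            return np.zeros(n_steps)
        out = np.full(n_steps, self.eta * dt)
        if self.eta_schedule:
            for t_on, factor in self.eta_schedule:
                out[int(round(t_on / dt)):] = self.eta * factor * dt
        return out


@dataclass
class NetworkState:
    """Full dynamical state of the two layers and every trace."""

    cmd_layer: LIFState
    rec_layer: LIFState
    cmd_traces: np.ndarray
    rec_traces: np.ndarray
    err_traces: np.ndarray
    learn_err_traces: np.ndarray
    time: float = 0.0

    def copy(self) -> "NetworkState":
        return NetworkState(
            self.cmd_layer.copy(), self.rec_layer.copy(),
            self.cmd_traces.copy(), self.rec_traces.copy(),
            self.err_traces.copy(), self.learn_err_traces.copy(), self.time,
        )


@dataclass
class PhaseRecord:
    """Decimated recordings of one ``run_phase`` call."""

    times: np.ndarray
    xhat: np.ndarray
    err: np.ndarray
    spike_counts_cmd: np.ndarray
    spike_counts_rec: np.ndarray
    duration: float
    dt: float
    record_every: int
    raster: np.ndarray | None = None
    snapshot_times: np.ndarray | None = None
    wff_snapshots: np.ndarray | None = None
    wrec_snapshots: np.ndarray | None = None

    @property
    def mean_rate_rec(self) -> float:
        return float(self.spike_counts_rec.mean() / self.duration)


class FollowNetwork:
    """Command layer -> plastic feedforward -> plastic recurrent layer with
    fixed readout and error feedback."""

    def __init__(
        self,
        cmd_ensemble: TuningEnsemble,
        rec_ensemble: TuningEnsemble,
        weights: WeightSet,
        tau_s: float = 0.020,
        neuron_params: NeuronParams = DEFAULT_PARAMS,
    ):
        if weights.w_ff.shape != (rec_ensemble.n_neurons, cmd_ensemble.n_neurons):
            raise ValueError("w_ff shape does not match the ensembles")
        if neuron_params.v_reset != 0.0:
            raise ValueError("the simulator assumes v_reset == 0")
        self.cmd_ensemble = cmd_ensemble
        self.rec_ensemble = rec_ensemble
        self.weights = weights
        self.tau_s = tau_s
        self.neuron_params = neuron_params
        self._Ecmd = cmd_ensemble.weighted_encoders()
        self.dim_cmd = cmd_ensemble.dim
        self.dim_out = weights.decoders.shape[0]

    # ------------------------------------------------------------------
    def init_state(self) -> NetworkState:
        n_cmd = self.cmd_ensemble.n_neurons
        n_rec = self.rec_ensemble.n_neurons
        return NetworkState(
            cmd_layer=LIFState.zeros(n_cmd),
            rec_layer=LIFState.zeros(n_rec),
            cmd_traces=np.zeros(n_cmd),
            rec_traces=np.zeros(n_rec),
            err_traces=np.zeros(self.dim_out),
            learn_err_traces=np.zeros(n_rec),
        )

    # ------------------------------------------------------------------
    def command_currents(self, u: np.ndarray) -> np.ndarray:
        """Currents into the command layer: J_l = e_ff_l . u + b_l."""
        u = np.asarray(u, dtype=float)
        if u.shape[-1] != self.dim_cmd:
            raise ValueError("command dimension mismatch")
        return self._Ecmd @ u + self.cmd_ensemble.biases

    def recurrent_currents(self, state: NetworkState,
                           feedback_on: bool = True) -> np.ndarray:
        """Currents into the recurrent layer from traces updated so far."""
        w = self.weights
        J = (w.w_ff @ state.cmd_traces + w.w_rec @ state.rec_traces
             + self.rec_ensemble.biases)
        if feedback_on:
            J = J + w.fb_gain * (w.fb_encoders @ state.err_traces)
        return J

    def decode(self, rec_traces: np.ndarray) -> np.ndarray:
        return self.weights.decoders @ rec_traces

    def follow_update(self, learn_err_traces, pre_traces_cmd, pre_traces_rec,
                      eta: float, dt: float) -> tuple[np.ndarray, np.ndarray]:
        """Weight increments of one tick (rank-1 per layer); masks applied.

        The per-synapse coefficient is ``eta * dt / n_pre`` where ``n_pre`` is
        the presynaptic population size — the parameterization of the original
        simulator's error-driven rule, which makes the learning speed of the
        decoded output independent of how many neurons carry it.  The printed
        learning rates (e.g. 2e-4) are in these units.
        """
        n_cmd = pre_traces_cmd.shape[0]
        n_rec = pre_traces_rec.shape[0]
        d_ff = (eta * dt / n_cmd) * np.outer(learn_err_traces, pre_traces_cmd)
        d_rec = (eta * dt / n_rec) * np.outer(learn_err_traces, pre_traces_rec)
        if self.weights.mask_ff is not None:
            d_ff *= self.weights.mask_ff
        if self.weights.mask_rec is not None:
            d_rec *= self.weights.mask_rec
        return d_ff, d_rec

    # ------------------------------------------------------------------
    def step(
        self,
        state: NetworkState,
        u: np.ndarray,
        x_ref: np.ndarray,
        dt: float,
        cfg: LearnConfig,
        noise: np.ndarray | None = None,
        eta_dt: float | None = None,
    ):
        """One closed-loop tick (reference numpy implementation).

        ``x_ref`` is the reference value at the error node for this tick
        (already filtered/delayed by the caller).  Returns
        ``(state, xhat, eps, spikes_cmd, spikes_rec)``; ``state`` is modified
        in place.
        """
        p = self.neuron_params
        w = self.weights
        decay_s = np.exp(-dt / self.tau_s)
        decay_eps = np.exp(-dt / cfg.tau_eps)

        # (i)-(ii) command layer
        Jc = self.command_currents(u)
        _, spikes_cmd = lif_step(state.cmd_layer, Jc, dt, p)
        state.cmd_traces *= decay_s
        state.cmd_traces += spikes_cmd / self.tau_s
        state.cmd_traces[state.cmd_traces <= 1e-12] = 0.0

        # (iii)-(iv) recurrent layer (previous-tick rec/err traces)
        J = self.recurrent_currents(state, feedback_on=cfg.feedback_on)
        _, spikes_rec = lif_step(state.rec_layer, J, dt, p)
        pre_rec = state.rec_traces * decay_s + spikes_rec / self.tau_s
        pre_rec[pre_rec <= 1e-12] = 0.0
        state.rec_traces = pre_rec

        # (v)-(vi) decode and compare
        xhat = self.decode(state.rec_traces)
        eps = np.asarray(x_ref, dtype=float) - xhat
        if noise is not None:
            eps = eps + noise

        # (vii) error traces
        state.err_traces *= decay_s
        state.err_traces += eps * (1.0 - decay_s)
        i_eps = w.fb_gain * (w.fb_encoders @ eps)
        state.learn_err_traces *= decay_eps
        state.learn_err_traces += i_eps * (1.0 - decay_eps)
        state.learn_err_traces[np.abs(state.learn_err_traces) <= 1e-12] = 0.0

        # (viii) plasticity
        if cfg.plasticity_on:
            e_dt = cfg.eta * dt if eta_dt is None else eta_dt
            if e_dt != 0.0:
                d_ff, d_rec = self.follow_update(
                    state.learn_err_traces, state.cmd_traces, state.rec_traces,
                    1.0, e_dt,
                )
                w.w_ff += d_ff
                w.w_rec += d_rec
        state.time += dt
        return state, xhat, eps, spikes_cmd, spikes_rec

    # ------------------------------------------------------------------
    def run_phase(
        self,
        state: NetworkState,
        u_series: np.ndarray,
        xref_series: np.ndarray,
        dt: float,
        cfg: LearnConfig,
        record_every: int = 10,
        record_spikes: bool = False,
        snapshot_every: float | None = None,
        noise_rng: np.random.Generator | None = None,
    ) -> PhaseRecord:
        """Run many ticks through the compiled kernel.

        ``xref_series`` (T, Nd) is the signal at the error node (the caller is
        responsible for reference filtering and delays, which are series-level
        operations).  Deterministic given the state, the inputs and the noise
        generator.
        """
        u_series = np.ascontiguousarray(u_series, dtype=float)
        xref_series = np.ascontiguousarray(xref_series, dtype=float)
        T = u_series.shape[0]
        if xref_series.shape != (T, self.dim_out):
            raise ValueError("xref_series shape mismatch")
        if T == 0:
            return PhaseRecord(
                times=np.empty(0), xhat=np.empty((0, self.dim_out)),
                err=np.empty((0, self.dim_out)),
                spike_counts_cmd=np.zeros(self.cmd_ensemble.n_neurons, np.int64),
                spike_counts_rec=np.zeros(self.rec_ensemble.n_neurons, np.int64),
                duration=0.0, dt=dt, record_every=record_every,
            )
        w = self.weights
        n_rec = self.rec_ensemble.n_neurons

        if cfg.error_noise_sigma > 0.0:
            if noise_rng is None:
                raise ValueError("error_noise_sigma > 0 requires noise_rng")
            noise = noise_rng.normal(0.0, cfg.error_noise_sigma,
                                     size=(T, self.dim_out))
        else:
            noise = np.zeros((T, self.dim_out))

        eta_dt = cfg.eta_series(T, dt)
        M = -(-T // record_every)
        xhat_out = np.zeros((M, self.dim_out))
        err_out = np.zeros((M, self.dim_out))
        counts_cmd = np.zeros(self.cmd_ensemble.n_neurons, np.int64)
        counts_rec = np.zeros(n_rec, np.int64)
        raster = (np.zeros((T, n_rec), np.uint8) if record_spikes
                  else np.zeros((1, 1), np.uint8))
        if snapshot_every is not None:
            snap_steps = int(round(snapshot_every / dt))
            n_snaps = T // snap_steps
            wff_snaps = np.zeros((n_snaps,) + w.w_ff.shape)
            wrec_snaps = np.zeros((n_snaps,) + w.w_rec.shape)
        else:
            snap_steps = 0
            wff_snaps = np.zeros((0, 1, 1))
            wrec_snaps = np.zeros((0, 1, 1))

        dummy = np.ones((1, 1))
        p = self.neuron_params
        run_phase_kernel(
            dt,
            np.ascontiguousarray(self._Ecmd), self.cmd_ensemble.biases,
            np.ascontiguousarray(w.fb_encoders), self.rec_ensemble.biases,
            np.ascontiguousarray(w.decoders),
            w.w_ff, w.w_rec,
            w.mask_ff is not None, w.mask_ff if w.mask_ff is not None else dummy,
            w.mask_rec is not None, w.mask_rec if w.mask_rec is not None else dummy,
            w.fb_gain if cfg.feedback_on else 0.0, w.fb_gain,
            1.0 / self.cmd_ensemble.n_neurons, 1.0 / n_rec,
            eta_dt,
            u_series, xref_series, noise,
            p.tau_m, p.tau_r, p.threshold, p.v_floor,
            np.exp(-dt / self.tau_s), 1.0 / self.tau_s,
            1.0 - np.exp(-dt / self.tau_s),
            np.exp(-dt / cfg.tau_eps), 1.0 - np.exp(-dt / cfg.tau_eps),
            state.cmd_layer.voltages, state.cmd_layer.refractory_remaining,
            state.rec_layer.voltages, state.rec_layer.refractory_remaining,
            state.cmd_traces, state.rec_traces,
            state.err_traces, state.learn_err_traces,
            record_every, xhat_out, err_out,
            counts_cmd, counts_rec,
            record_spikes, raster,
            snap_steps, wff_snaps, wrec_snaps,
        )
        if not np.all(np.isfinite(xhat_out)):
            raise FloatingPointError(
                "non-finite network output; numerical blow-up during the phase"
            )
        t0 = state.time
        state.time += T * dt
        return PhaseRecord(
            times=t0 + np.arange(0, T, record_every) * dt,
            xhat=xhat_out, err=err_out,
            spike_counts_cmd=counts_cmd, spike_counts_rec=counts_rec,
            duration=T * dt, dt=dt, record_every=record_every,
            raster=raster if record_spikes else None,
            snapshot_times=(t0 + (np.arange(wff_snaps.shape[0]) + 1)
                            * snap_steps * dt if snap_steps else None),
            wff_snapshots=wff_snaps if snap_steps else None,
            wrec_snapshots=wrec_snaps if snap_steps else None,
        )
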