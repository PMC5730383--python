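"""Scripted experimental protocols: learning curves, open-loop tests,
realizable-reference recovery, readout relearning, robustness sweeps, and
Lorenz attractor statistics.

The canonical protocol has three phases sharing one continuous reference
trajectory: a short pre-learning phase (feedback and plasticity off — the
output stays at zero), a learning phase (feedback on with gain k, FOLLOW
plasticity on, babbling command input), and an open-loop testing phase
(feedback and plasticity off) where the trained network must predict the
reference on its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import readout_learn_kernel
from .autoencoder import solve_decoders
from .config import SYSTEM_TABLE, expand_seed
from .lif import sample_tuning
from .network import FollowNetwork, LearnConfig, PhaseRecord, WeightSet
from .reference_systems import integrate_reference, make_reference
from .signals import (BabblingConfig, babbling_input, delay_series,
                      filter_series, lorenz_kick, pulse_pedestal_input,
                      ramp_step_input)

__all__ = [
    "ProtocolResult", "SweepResult", "build_network", "learning_protocol",
    "mse_blocks", "rate_histogram", "weight_r2", "realizable_protocol",
    "readout_relearn", "robustness_sweep", "tent_map", "spike_alignment",
]


@dataclass
class ProtocolResult:
    """Recordings and metrics of one three-phase run."""

    phases: dict[str, PhaseRecord]
    xref: dict[str, np.ndarray]          # decimated reference per phase
    u: dict[str, np.ndarray]             # decimated command per phase
    block_mse: np.ndarray                # per-4 s MSE during learning
    block_duration: float
    config: dict
    network: FollowNetwork | None = None

    @property
    def final_block_mse(self) -> float:
        return float(self.block_mse[-1])

    @property
    def first_block_mse(self) -> float:
        return float(self.block_mse[0])


@dataclass
class SweepResult:
    """Final mean-squared errors of a one-parameter robustness sweep."""

    axis: str
    values: np.ndarray
    final_mse: np.ndarray                # (n_values, n_seeds)
    seeds: np.ndarray


def mse_blocks(err: np.ndarray, dt: float, block: float = 4.0) -> np.ndarray:
    """Mean squared error per dimension, averaged over consecutive blocks.

    ``err`` has shape (T, Nd) sampled at interval ``dt``; partial trailing
    blocks are dropped.
    """
    err = np.asarray(err, dtype=float)
    per_block = int(round(block / dt))
    if err.shape[0] < per_block:
        raise ValueError("error series shorter than one block")
    n_blocks = err.shape[0] // per_block
    e2 = (err[: n_blocks * per_block] ** 2).mean(axis=1)
    return e2.reshape(n_blocks, per_block).mean(axis=1)


def rate_histogram(raster: np.ndarray, dt: float, t0: float = 0.0,
                   window: float = 0.25, bins: int = 50) -> dict:
    """Per-neuron firing rates in ``[t0, t0 + window)`` from a spike raster.

    ``raster`` is (T, N) with 0/1 spike indicators at resolution ``dt``.
    Returns the rates, their mean across neurons, and a histogram.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    i0 = int(round(t0 / dt))
    i1 = i0 + int(round(window / dt))
    counts = np.asarray(raster[i0:i1], dtype=float).sum(axis=0)
    rates = counts / window
    hist, edges = np.histogram(rates, bins=bins)
    return {"rates": rates, "mean_rate": float(rates.mean()),
            "hist": hist, "bin_edges": edges}


def weight_r2(learned: np.ndarray, reference: np.ndarray) -> float:
    """Coefficient of determination of the fit of ``learned`` to the identity
    line against ``reference`` (1 = perfect weight recovery)."""
    learned = np.asarray(learned, float).ravel()
    reference = np.asarray(reference, float).ravel()
    if learned.shape != reference.shape:
        raise ValueError("weight matrices must have the same shape")
    ss_res = np.sum((learned - reference) ** 2)
    ss_tot = np.sum((reference - reference.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("zero-variance reference weights")
    return float(1.0 - ss_res / ss_tot)


def tent_map(x3: np.ndarray) -> np.ndarray:
    """Pairs of consecutive strict local maxima of a scalar series.

    For the third Lorenz coordinate this traces the classic single-humped
    'tent' return map.  Returns an (n_pairs, 2) array of
    ``(max_n, max_{n+1})``; empty if fewer than two maxima exist.
    """
    x3 = np.asarray(x3, dtype=float)
    if x3.size < 3:
        return np.empty((0, 2))
    interior = (x3[1:-1] > x3[:-2]) & (x3[1:-1] > x3[2:])
    maxima = x3[1:-1][interior]
    if maxima.size < 2:
        return np.empty((0, 2))
    return np.column_stack([maxima[:-1], maxima[1:]])


def spike_alignment(raster_a: np.ndarray, raster_b: np.ndarray, dt: float,
                    tol: float = 0.002) -> float:
    """Fraction of spikes in ``raster_a`` with a spike of the same neuron in
    ``raster_b`` within ``+/- tol`` seconds."""
    ksteps = int(round(tol / dt))
    a = np.asarray(raster_a, bool)
    near = np.asarray(raster_b, bool).copy()
    for shift in range(1, ksteps + 1):
        near[shift:] |= raster_b[:-shift].astype(bool)
        near[:-shift] |= raster_b[shift:].astype(bool)
    n_spikes = a.sum()
    if n_spikes == 0:
        return float("nan")
    return float((a & near).sum() / n_spikes)


# ----------------------------------------------------------------------
def build_network(
    system: str = "vdp",
    n_neurons: int = 1000,
    n_cmd_neurons: int | None = None,
    tuning_scheme: str = "intercept_maxrate",
    k: float = 10.0,
    seed: int = 0,
    connectivity: float = 1.0,
    decoder_perturb: tuple[float, float] | None = None,
    radius_cmd: float | None = None,
    radius_rec: float | None = None,
    tau_s: float = 0.020,
) -> tuple[FollowNetwork, list[np.random.Generator]]:
    """Construct the two-layer network for a reference system.

    Returns the network and the remaining seeded generators
    ``[input_rng, noise_rng]``.
    """
    table = SYSTEM_TABLE[system]
    spec = make_reference(system)
    R1 = table["radius_cmd"] if radius_cmd is None else radius_cmd
    R2 = table["radius_rec"] if radius_rec is None else radius_rec
    n_cmd = n_neurons if n_cmd_neurons is None else n_cmd_neurons
    rng_tune, rng_dec, rng_in, rng_noise = expand_seed(seed, 4)

    cmd_ens = sample_tuning(n_cmd, spec.dim_cmd, R1, tuning_scheme, rng_tune)
    rec_ens = sample_tuning(n_neurons, spec.dim, R2, tuning_scheme, rng_tune)
    dec = solve_decoders(rec_ens, rng=rng_dec)
    weights = WeightSet.zeros(
        cmd_ens, rec_ens, dec.decoders, fb_gain=k,
        connectivity=connectivity, decoder_perturb=decoder_perturb,
        rng=rng_noise,
    )
    net = FollowNetwork(cmd_ens, rec_ens, weights, tau_s=tau_s)
    return net, [rng_in, rng_noise]


def _protocol_input(system: str, table: dict, duration: float, dt: float,
                    rng: np.random.Generator, dim_cmd: int,
                    zeta1=None, zeta2=None, t_period=None) -> np.ndarray:
    z1 = table["zeta1"] if zeta1 is None else zeta1
    z2 = table["zeta2"] if zeta2 is None else zeta2
    tp = table["t_period"] if t_period is None else t_period
    if table.get("kick_only"):
        return lorenz_kick(np.max(np.asarray(z1)), duration, dt, rng, dim=dim_cmd)
    cfg = BabblingConfig(zeta1=np.asarray(z1, float), zeta2=np.asarray(z2, float),
                         pedestal_period=tp, interpolate=table.get("interpolate", False))
    return babbling_input(cfg, duration, dt, rng, dim=dim_cmd)


def learning_protocol(
    system: str = "vdp",
    *,
    n_neurons: int = 1000,
    n_cmd_neurons: int | None = None,
    t_pre: float = 4.0,
    t_learn: float = 500.0,
    t_test: float = 16.0,
    dt: float = 1e-3,
    seed: int = 0,
    k: float = 10.0,
    eta: float | None = None,
    eta_schedule: list[tuple[float, float]] | None = None,
    tuning_scheme: str = "intercept_maxrate",
    tau_eps: float = 0.200,
    connectivity: float = 1.0,
    decoder_perturb: tuple[float, float] | None = None,
    error_noise_sigma: float = 0.0,
    reference_delay: float = 0.0,
    compensate_command_delay: bool = False,
    zeta1=None,
    zeta2=None,
    t_period: float | None = None,
    record_every: int = 10,
    record_spikes_test: bool = False,
    snapshot_every: float | None = None,
    test_input: str = "babbling",
    xref_override: np.ndarray | None = None,
    network: FollowNetwork | None = None,
    input_rng: np.random.Generator | None = None,
    noise_rng: np.random.Generator | None = None,
    keep_network: bool = True,
) -> ProtocolResult:
    """Run the three-phase learning protocol against a reference system.

    Phase 1 (``t_pre``): feedback off, plasticity off.  Phase 2 (``t_learn``):
    feedback on with gain ``k`` and FOLLOW plasticity on, babbling input.
    Phase 3 (``t_test``): open loop (feedback and plasticity off) on fresh
    input of the same statistics.  All phases share one continuous reference
    trajectory and one reference filter state.

    ``xref_override`` replaces the integrated ODE reference by a caller-
    supplied trajectory of the same length (used for realizable-network
    references); it is still passed through the reference filter when the
    system's default says so.
    """
    table = SYSTEM_TABLE[system]
    spec = make_reference(system)
    if eta is None:
        eta = table["eta"]
    if network is None:
        network, (rng_in, rng_noise) = build_network(
            system, n_neurons, n_cmd_neurons, tuning_scheme, k, seed,
            connectivity, decoder_perturb,
        )
    else:
        _, _, rng_in, rng_noise = expand_seed(seed, 4)
    input_rng = rng_in if input_rng is None else input_rng
    noise_rng = rng_noise if noise_rng is None else noise_rng

    n_pre = int(round(t_pre / dt))
    n_learn = int(round(t_learn / dt))
    n_test = int(round(t_test / dt))

    u_parts = []
    for phase_name, tt in (("pre", t_pre), ("learn", t_learn),
                           ("test", t_test)):
        if tt <= 0:
            continue
        if phase_name == "test" and test_input != "babbling":
            z1 = np.max(np.asarray(table["zeta1"] if zeta1 is None else zeta1))
            z2 = np.max(np.asarray(table["zeta2"] if zeta2 is None else zeta2))
            if test_input == "pulse_pedestal":
                u_parts.append(pulse_pedestal_input(
                    tt, dt, input_rng, dim=spec.dim_cmd,
                    pulse_amp=z1, pedestal_amp=max(z2, z1)))
            elif test_input == "ramp_step":
                u_parts.append(ramp_step_input(tt, dt, dim=spec.dim_cmd,
                                               level=max(z2, z1)))
            else:
                raise ValueError(f"unknown test_input {test_input!r}")
        else:
            u_parts.append(_protocol_input(system, table, tt, dt, input_rng,
                                           spec.dim_cmd, zeta1, zeta2,
                                           t_period))
    u_full = np.concatenate(u_parts) if u_parts else np.zeros((0, spec.dim_cmd))
    T = u_full.shape[0]

    if xref_override is not None:
        xref_raw = np.asarray(xref_override, dtype=float)
        if xref_raw.shape != (T, spec.dim):
            raise ValueError("xref_override shape mismatch")
    else:
        xref_raw = integrate_reference(spec, u_full, dt)
    xref_node = (filter_series(xref_raw, network.tau_s, dt)
                 if spec.filter_reference else xref_raw)
    if reference_delay > 0:
        xref_node = delay_series(xref_node, reference_delay, dt)
    u_net = (delay_series(u_full, reference_delay, dt)
             if (reference_delay > 0 and compensate_command_delay) else u_full)

    state = network.init_state()
    phases: dict[str, PhaseRecord] = {}
    xref_rec: dict[str, np.ndarray] = {}
    u_rec: dict[str, np.ndarray] = {}
    bounds = {"pre": (0, n_pre), "learn": (n_pre, n_pre + n_learn),
              "test": (n_pre + n_learn, n_pre + n_learn + n_test)}
    cfgs = {
        "pre": LearnConfig(eta=0.0, feedback_on=False, plasticity_on=False,
                           tau_eps=tau_eps),
        "learn": LearnConfig(eta=eta, eta_schedule=eta_schedule,
                             feedback_on=True, plasticity_on=True,
                             tau_eps=tau_eps,
                             error_noise_sigma=error_noise_sigma),
        "test": LearnConfig(eta=0.0, feedback_on=False, plasticity_on=False,
                            tau_eps=tau_eps),
    }
    for name, (i0, i1) in bounds.items():
        if i1 == i0:
            continue
        phases[name] = network.run_phase(
            state, u_net[i0:i1], xref_node[i0:i1], dt, cfgs[name],
            record_every=record_every,
            record_spikes=(record_spikes_test and name == "test"),
            snapshot_every=snapshot_every if name == "learn" else None,
            noise_rng=noise_rng,
        )
        xref_rec[name] = xref_node[i0:i1:record_every]
        u_rec[name] = u_net[i0:i1:record_every]

    if "learn" in phases and t_learn >= 4.0:
        block = mse_blocks(phases["learn"].err, dt * record_every, block=4.0)
    else:
        block = np.empty(0)
    return ProtocolResult(
        phases=phases, xref=xref_rec, u=u_rec,
        block_mse=block, block_duration=4.0,
        config=dict(system=system, n_neurons=n_neurons, t_pre=t_pre,
                    t_learn=t_learn, t_test=t_test, dt=dt, seed=seed, k=k,
                    eta=eta, eta_schedule=eta_schedule,
                    tuning_scheme=tuning_scheme,
                    connectivity=connectivity,
                    decoder_perturb=decoder_perturb,
                    error_noise_sigma=error_noise_sigma,
                    reference_delay=reference_delay,
                    compensate_command_delay=compensate_command_delay),
        network=network if keep_network else None,
    )


# ----------------------------------------------------------------------
def realizable_protocol(
    system: str = "linear",
    *,
    n_neurons: int = 200,
    t_train_reference: float = 200.0,
    t_learn: float = 200.0,
    dt: float = 1e-3,
    seed: int = 0,
    k: float = 10.0,
    eta: float | None = None,
    snapshot_every: float | None = 50.0,
    t_align: float = 2.0,
    compare_ode: bool = True,
) -> dict:
    """Learn a frozen FOLLOW-trained spiking network as the reference.

    A reference network is first trained on the ODE system, then frozen; a
    learner with identical neurons, encoders and decoders but zero plastic
    weights is trained with FOLLOW against the frozen network's decoded output.
    Because the target is realizable, exact solution weights exist, and the
    learner's weights should converge toward them.

    Returns weight R-squared over learning time, the learner's block-MSE
    curve, a matched ODE-reference run for comparison (same duration, same
    seeds), and a spike-time alignment score under identical input with
    feedback on.
    """
    table = SYSTEM_TABLE[system]
    spec = make_reference(system)
    if eta is None:
        eta = table["eta"]

    ref_result = learning_protocol(
        system, n_neurons=n_neurons, t_pre=0.0, t_learn=t_train_reference,
        t_test=0.0, dt=dt, seed=seed, k=k, eta=eta, keep_network=True,
    )
    ref_net = ref_result.network
    ref_weights = ref_net.weights.copy()

    # Frozen reference network generates the target trajectory open loop.
    _, _, input_rng, noise_rng = expand_seed(seed + 1, 4)
    n_steps = int(round(t_learn / dt))
    u = _protocol_input(system, table, t_learn, dt, input_rng, spec.dim_cmd)
    frozen_cfg = LearnConfig(eta=0.0, feedback_on=False, plasticity_on=False)
    ref_rec = ref_net.run_phase(ref_net.init_state(), u,
                                np.zeros((n_steps, spec.dim)), dt, frozen_cfg,
                                record_every=1)
    x_star = ref_rec.xhat

    # Learner: identical ensembles and decoders, plastic weights from zero.
    learner = FollowNetwork(
        ref_net.cmd_ensemble, ref_net.rec_ensemble,
        WeightSet.zeros(ref_net.cmd_ensemble, ref_net.rec_ensemble,
                        ref_net.weights.decoders, fb_gain=k),
        tau_s=ref_net.tau_s,
    )
    xref_node = (filter_series(x_star, learner.tau_s, dt)
                 if spec.filter_reference else x_star)
    learn_cfg = LearnConfig(eta=eta, feedback_on=True, plasticity_on=True)
    learn_rec = learner.run_phase(learner.init_state(), u, xref_node, dt,
                                  learn_cfg, record_every=10,
                                  snapshot_every=snapshot_every)

    r2_ff = [weight_r2(w, ref_weights.w_ff)
             for w in learn_rec.wff_snapshots]
    r2_rec = [weight_r2(w, ref_weights.w_rec)
              for w in learn_rec.wrec_snapshots]
    block = mse_blocks(learn_rec.err, dt * 10, block=4.0)

    out = {
        "reference_weights": ref_weights,
        "learner_weights": learner.weights,
        "snapshot_times": learn_rec.snapshot_times,
        "weight_r2_ff": np.array(r2_ff),
        "weight_r2_rec": np.array(r2_rec),
        "block_mse": block,
        "reference_training": ref_result,
    }

    if compare_ode:
        # matched run against the ODE reference: identical ensembles,
        # decoders and input stream (seed + 1 reproduces the learner's input)
        ode_result = learning_protocol(
            system, n_neurons=n_neurons, t_pre=0.0, t_learn=t_learn,
            t_test=0.0, dt=dt, seed=seed + 1, k=k, eta=eta,
            network=FollowNetwork(
                ref_net.cmd_ensemble, ref_net.rec_ensemble,
                WeightSet.zeros(ref_net.cmd_ensemble, ref_net.rec_ensemble,
                                ref_net.weights.decoders, fb_gain=k),
                tau_s=ref_net.tau_s),
            keep_network=False,
        )
        out["block_mse_ode"] = ode_result.block_mse

    if t_align > 0:
        n_al = int(round(t_align / dt))
        u_al = _protocol_input(system, table, t_align, dt, input_rng,
                               spec.dim_cmd)
        ref_al = ref_net.run_phase(ref_net.init_state(), u_al,
                                   np.zeros((n_al, spec.dim)), dt, frozen_cfg,
                                   record_every=1, record_spikes=True)
        x_star_al = ref_al.xhat
        xref_al = (filter_series(x_star_al, learner.tau_s, dt)
                   if spec.filter_reference else x_star_al)
        fb_cfg = LearnConfig(eta=0.0, feedback_on=True, plasticity_on=False)
        learn_al = learner.run_phase(learner.init_state(), u_al, xref_al, dt,
                                     fb_cfg, record_every=1,
                                     record_spikes=True)
        out["spike_alignment"] = spike_alignment(
            learn_al.raster, ref_al.raster, dt, tol=0.002)
    return out


# ----------------------------------------------------------------------
def readout_relearn(
    network: FollowNetwork,
    system: str,
    *,
    shuffle: bool = False,
    duration: float = 50.0,
    dt: float = 1e-3,
    eta_r: float = 1e-4,
    seed: int = 0,
    record_every: int = 100,
) -> dict:
    """Relearn readout weights from zero with a perceptron rule.

    The network (with its learned — or entry-shuffled — plastic weights) is
    run in closed loop against the ODE reference; fresh readout weights are
    then trained online on the recorded spike trains, with the network's own
    decoded output as the target.  A network whose specific weight matrix
    matters (not just the weight distribution) supports relearning only in the
    unshuffled condition.
    """
    table = SYSTEM_TABLE[system]
    spec = make_reference(system)
    _, _, input_rng, noise_rng = expand_seed(seed + 17, 4)

    weights = network.weights.copy()
    if shuffle:
        rng = np.random.default_rng(seed + 23)
        for m in (weights.w_ff, weights.w_rec):
            nz = m != 0.0
            vals = m[nz]
            rng.shuffle(vals)
            m[nz] = vals
    net = FollowNetwork(network.cmd_ensemble, network.rec_ensemble, weights,
                        tau_s=network.tau_s)

    n_steps = int(round(duration / dt))
    u = _protocol_input(system, table, duration, dt, input_rng, spec.dim_cmd)
    xref = integrate_reference(spec, u, dt)
    xref_node = (filter_series(xref, net.tau_s, dt)
                 if spec.filter_reference else xref)
    cfg = LearnConfig(eta=0.0, feedback_on=True, plasticity_on=False)
    rec = net.run_phase(net.init_state(), u, xref_node, dt, cfg,
                        record_every=1, record_spikes=True)
    target = rec.xhat  # output of the network through its true decoders

    d = np.zeros_like(net.weights.decoders)
    n_out = -(-n_steps // record_every)
    err_out = np.zeros(n_out)
    readout_learn_kernel(rec.raster, target, d, net.tau_s, dt, eta_r,
                         err_out, record_every)
    n_tail = max(1, n_out // 5)
    scale = np.linalg.norm(target, axis=1).mean()
    return {
        "readout": d,
        "error_curve": err_out,
        "final_error": float(err_out[-n_tail:].mean()),
        "final_relative_error": float(err_out[-n_tail:].mean() / scale),
        "target_scale": float(scale),
    }


# ----------------------------------------------------------------------
_SWEEP_AXES = ("connectivity", "error_noise", "decoder_chi", "decoder_xi",
               "delay", "delay_compensated")


def robustness_sweep(
    axis: str,
    values,
    *,
    system: str = "vdp",
    seeds=(0, 1, 2),
    final_window_frac: float = 0.2,
    chi_for_xi: float = 2.0,
    **protocol_kwargs,
) -> SweepResult:
    """Final-window mean squared error as one perturbation axis is varied.

    For each value and seed, runs the learning protocol with that perturbation
    and records the mean block-MSE over the final fraction of learning (the
    printed protocol used the last 400 s of a 10,000 s run, i.e. the last
    ~20%, which is what ``final_window_frac`` scales).
    """
    if axis not in _SWEEP_AXES:
        raise ValueError(f"axis must be one of {_SWEEP_AXES}")
    values = np.asarray(list(values), dtype=float)
    seeds = np.asarray(list(seeds), dtype=int)
    final = np.zeros((values.size, seeds.size))
    for iv, v in enumerate(values):
        for isd, sd in enumerate(seeds):
            kw = dict(protocol_kwargs)
            if axis == "connectivity":
                kw["connectivity"] = float(v)
            elif axis == "error_noise":
                kw["error_noise_sigma"] = float(v)
            elif axis == "decoder_chi":
                kw["decoder_perturb"] = (float(v), 0.0)
            elif axis == "decoder_xi":
                kw["decoder_perturb"] = (chi_for_xi, float(v))
            elif axis == "delay":
                kw["reference_delay"] = float(v)
            elif axis == "delay_compensated":
                kw["reference_delay"] = float(v)
                kw["compensate_command_delay"] = True
            res = learning_protocol(system, seed=int(sd), keep_network=False,
                                    **kw)
            n_tail = max(1, int(round(final_window_frac * res.block_mse.size)))
            final[iv, isd] = res.block_mse[-n_tail:].mean()
    return SweepResult(axis=axis, values=values, final_mse=final, seeds=seeds)
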