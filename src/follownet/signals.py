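"""Synaptic filters, babbling command inputs, delay lines and noise.

All spike trains in the network are low-pass filtered at the synapse with an
exponential kernel ``kappa(t) = exp(-t/tau)/tau`` of unit area; the same
kernel family (with a longer time constant) filters the error current used by
the plasticity rule.  The discrete update is the exact exponential one, so the
DC gain is exactly 1 at any step size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExpFilterState",
    "exp_filter_step",
    "filter_series",
    "BabblingConfig",
    "babbling_input",
    "lorenz_kick",
    "DelayLine",
    "delay_series",
    "gaussian_error_noise",
]


@dataclass
class ExpFilterState:
    """State of an exponential low-pass filter: time constant and trace."""

    tau: float
    trace: np.ndarray

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        self.trace = np.atleast_1d(np.asarray(self.trace, dtype=float))

    @classmethod
    def zeros(cls, tau: float, n: int) -> "ExpFilterState":
        return cls(tau, np.zeros(n))


def exp_filter_step(
    state: ExpFilterState,
    impulse_area=0.0,
    continuous_input=0.0,
    dt: float = 1e-3,
) -> ExpFilterState:
    """One tick of the exponential filter.

    The trace decays by ``exp(-dt/tau)``; spikes (impulses of given area) add
    ``area/tau``; continuous inputs enter through the exact zero-order-hold
    update ``input * (1 - exp(-dt/tau))`` which preserves unit DC gain.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    a = np.exp(-dt / state.tau)
    state.trace *= a
    state.trace += np.asarray(impulse_area) / state.tau
    state.trace += np.asarray(continuous_input) * (1.0 - a)
    return state


def filter_series(x: np.ndarray, tau: float, dt: float,
                  initial: np.ndarray | None = None) -> np.ndarray:
    """Filter a continuous time series (T, d) with the exponential kernel.

    Vectorized equivalent of repeated :func:`exp_filter_step` with
    ``continuous_input=x[t]`` at every tick.
    """
    from scipy.signal import lfilter

    x = np.asarray(x, dtype=float)
    a = np.exp(-dt / tau)
    zi = None
    if initial is not None:
        zi = (np.asarray(initial, dtype=float) * a)[None, :]
    y, _ = lfilter([1.0 - a], [1.0, -a], x, axis=0,
                   zi=zi if zi is not None else np.zeros((1, x.shape[1])))
    return y


@dataclass
class BabblingConfig:
    """Random 'motor babbling' command process.

    Every ``pulse_interval`` (50 ms) each component gets a fresh fast pulse
    drawn uniformly from (-zeta1, zeta1); every ``pedestal_period`` a slow
    pedestal vector is redrawn as ``zeta2`` times a uniformly random unit
    direction.  ``zeta1``/``zeta2`` may be per-component vectors, in which case
    each component is scaled by its own amplitude.  With ``interpolate`` the
    command is linearly interpolated between consecutive 50 ms draws instead of
    held piecewise constant (used for the arm, to avoid sharp transients).
    """

    zeta1: float | np.ndarray = 0.0
    zeta2: float | np.ndarray = 0.0
    pulse_interval: float = 0.050
    pedestal_period: float = 1.0
    interpolate: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.zeta1) < 0) or np.any(np.asarray(self.zeta2) < 0):
            raise ValueError("zeta amplitudes must be non-negative")
        if not self.pulse_interval > 0:
            raise ValueError("pulse_interval must be positive")
        if self.pedestal_period < self.pulse_interval:
            raise ValueError("pedestal_period must be >= pulse_interval")


def babbling_input(
    config: BabblingConfig,
    duration: float,
    dt: float,
    rng: np.random.Generator | None = None,
    dim: int = 2,
) -> np.ndarray:
    """Generate a babbling command series of shape (round(duration/dt), dim)."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_steps = int(round(duration / dt))
    pulse_steps = int(round(config.pulse_interval / dt))
    ped_steps = int(round(config.pedestal_period / dt))
    z1 = np.broadcast_to(np.asarray(config.zeta1, dtype=float), (dim,))
    z2 = np.broadcast_to(np.asarray(config.zeta2, dtype=float), (dim,))

    n_knots = -(-n_steps // pulse_steps) + 1  # one extra knot for interpolation
    knots = np.empty((n_knots, dim))
    pedestal = np.zeros(dim)
    for m in range(n_knots):
        t_step = m * pulse_steps
        if t_step % ped_steps == 0:
            direction = rng.standard_normal(dim)
            norm = np.linalg.norm(direction)
            direction = direction / norm if norm > 1e-12 else np.zeros(dim)
            pedestal = z2 * direction
        pulse = rng.uniform(-1.0, 1.0, size=dim) * z1
        knots[m] = pedestal + pulse

    u = np.empty((n_steps, dim))
    steps = np.arange(n_steps)
    if config.interpolate:
        knot_t = np.arange(n_knots) * pulse_steps
        for a in range(dim):
            u[:, a] = np.interp(steps, knot_t, knots[:, a])
    else:
        u[:] = knots[steps // pulse_steps]
    return u


def lorenz_kick(
    zeta1: float,
    duration: float,
    dt: float,
    rng: np.random.Generator | None = None,
    dim: int = 3,
    kick_duration: float = 0.250,
) -> np.ndarray:
    """Initial-kick input: a random direction of norm ``zeta1`` for the first
    250 ms, zero afterwards (used to set off the autonomous Lorenz system)."""
    if rng is None:
        rng = np.random.default_rng()
    n_steps = int(round(duration / dt))
    u = np.zeros((n_steps, dim))
    if zeta1 > 0:
        direction = rng.standard_normal(dim)
        direction /= np.linalg.norm(direction)
        u[: int(round(kick_duration / dt))] = zeta1 * direction
    return u


class DelayLine:
    """Pure delay of an integer number of steps, zero-initialized."""

    def __init__(self, delay: float, dt: float, dim: int = 1):
        if delay < 0:
            raise ValueError("delay must be non-negative")
        steps = int(round(delay / dt))
        if abs(steps * dt - delay) > 1e-9 * max(dt, 1.0):
            raise ValueError("delay must be an integer number of steps")
        self.n_steps = steps
        self._buf = np.zeros((max(steps, 1), dim))
        self._idx = 0

    def step(self, value: np.ndarray) -> np.ndarray:
        value = np.atleast_1d(np.asarray(value, dtype=float))
        if self.n_steps == 0:
            return value.copy()
        out = self._buf[self._idx].copy()
        self._buf[self._idx] = value
        self._idx = (self._idx + 1) % self.n_steps
        return out


def delay_series(x: np.ndarray, delay: float, dt: float) -> np.ndarray:
    """Shift a series (T, d) back in time by ``delay``, zero-padded at start."""
    steps = int(round(delay / dt))
    if steps == 0:
        return np.asarray(x, dtype=float).copy()
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    out[steps:] = x[:-steps]
    return out


def pulse_pedestal_input(
    duration: float,
    dt: float,
    rng: np.random.Generator,
    dim: int = 2,
    pulse_amp: float = 0.1,
    pedestal_amp: float = 0.05,
    pulse_width: float = 0.1,
    pedestal_period: float = 4.0,
) -> np.ndarray:
    """Open-loop test input: a sharp square pulse at the start of each
    pedestal segment, on constant pedestal levels redrawn every
    ``pedestal_period`` (used to probe a trained oscillator network)."""
    n_steps = int(round(duration / dt))
    ped_steps = int(round(pedestal_period / dt))
    pulse_steps = int(round(pulse_width / dt))
    u = np.empty((n_steps, dim))
    for start in range(0, n_steps, ped_steps):
        level = rng.uniform(-pedestal_amp, pedestal_amp, size=dim)
        u[start: start + ped_steps] = level
        stop = min(start + pulse_steps, n_steps)
        u[start:stop] += rng.uniform(-pulse_amp, pulse_amp, size=dim)
    return u


def ramp_step_input(
    duration: float,
    dt: float,
    dim: int = 2,
    level: np.ndarray | float = 0.05,
    ramp_time: float = 2.0,
) -> np.ndarray:
    """Open-loop test input: a ramp over ``ramp_time`` followed by a step to
    a constant level (a preparatory input before initiating movement)."""
    n_steps = int(round(duration / dt))
    level = np.broadcast_to(np.asarray(level, dtype=float), (dim,))
    t = np.arange(n_steps) * dt
    shape = np.clip(t / ramp_time, 0.0, 1.0)
    return shape[:, None] * level[None, :]


def gaussian_error_noise(
    sigma: float, shape, rng: np.random.Generator
) -> np.ndarray:
    """I.i.d. per-step Gaussian noise of standard deviation ``sigma``."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return np.zeros(shape)
    return rng.normal(0.0, sigma, size=shape)
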