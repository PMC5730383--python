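"""Leaky integrate-and-fire neurons and heterogeneous population tuning.

The populations used throughout this package follow the Neural Engineering
Framework convention: each neuron ``i`` sees a current that is an affine
function of the represented low-dimensional variable,

    J_i = nu_i * (e~_i . x) + b_i,

where ``e~_i`` is a 'normalized' encoding vector of norm ``1/R`` (so the
projection lies in [-1, 1] for ``|x| <= R``), ``nu_i > 0`` is a gain and
``b_i`` a bias.  Heterogeneity of gains and biases gives every neuron a
different tuning curve; a large population then forms a basis of non-linear
functions over the representation ball from which smooth functions can be
decoded linearly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NeuronParams",
    "TuningEnsemble",
    "LIFState",
    "lif_rate",
    "lif_step",
    "sample_tuning",
    "static_rates",
]


@dataclass(frozen=True)
class NeuronParams:
    """Parameters of the deterministic LIF neuron.

    tau_m : membrane time constant (s)
    tau_r : absolute refractory period (s)
    threshold : firing threshold (dimensionless voltage)
    v_reset : voltage after a spike
    v_floor : lower clip on the voltage
    """

    tau_m: float = 0.020
    tau_r: float = 0.002
    threshold: float = 1.0
    v_reset: float = 0.0
    v_floor: float = 0.0

    def __post_init__(self) -> None:
        if not self.tau_m > 0:
            raise ValueError("tau_m must be positive")
        if self.tau_r < 0:
            raise ValueError("tau_r must be non-negative")
        if not self.threshold > 0:
            raise ValueError("threshold must be positive")
        if not (self.v_reset <= self.v_floor <= self.threshold):
            raise ValueError("need v_reset <= v_floor <= threshold")


DEFAULT_PARAMS = NeuronParams()


def lif_rate(J, params: NeuronParams = DEFAULT_PARAMS):
    """Steady-state firing rate (Hz) of a LIF neuron driven by constant current.

    Zero below the rheobase ``threshold``; above it,
    ``1 / (tau_r + tau_m * ln(J / (J - threshold)))``.  Total function of any
    finite ``J`` (scalar or array).
    """
    J = np.asarray(J, dtype=float)
    if not np.all(np.isfinite(J)):
        raise ValueError("non-finite input current")
    theta = params.threshold
    out = np.zeros_like(J)
    above = J > theta
    Ja = J[above] if J.ndim else (J if above else None)
    if J.ndim == 0:
        if above:
            return float(1.0 / (params.tau_r + params.tau_m * np.log(J / (J - theta))))
        return 0.0
    out[above] = 1.0 / (params.tau_r + params.tau_m * np.log(Ja / (Ja - theta)))
    return out


@dataclass
class LIFState:
    """Membrane voltages and per-neuron refractory clocks (s)."""

    voltages: np.ndarray
    refractory_remaining: np.ndarray

    @classmethod
    def zeros(cls, n: int, dtype=np.float64) -> "LIFState":
        return cls(np.zeros(n, dtype=dtype), np.zeros(n, dtype=dtype))

    def copy(self) -> "LIFState":
        return LIFState(self.voltages.copy(), self.refractory_remaining.copy())


def lif_step(state: LIFState, J: np.ndarray, dt: float,
             params: NeuronParams = DEFAULT_PARAMS):
    """Advance a LIF population one step of size ``dt`` under currents ``J``.

    Uses the exact exponential voltage update over the non-refractory fraction
    of the step.  When the voltage crosses threshold within a step, the exact
    crossing time is interpolated and the refractory clock is charged from that
    instant, so steady-state rates under constant current match :func:`lif_rate`
    without step-size quantization bias (the scheme of the original simulator).

    Returns ``(state, spikes)`` with ``spikes`` a float vector of 0/1 impulse
    indicators (each spike carries unit area).
    """
    J = np.asarray(J)
    if not np.all(np.isfinite(J)):
        raise FloatingPointError("non-finite input current to LIF population")
    if dt <= 0:
        raise ValueError("dt must be positive")
    v = state.voltages
    ref = state.refractory_remaining

    ref -= dt
    np.clip(ref, 0.0, None, out=ref)
    # effective integration time within this step
    delta_t = np.clip(dt - ref, 0.0, dt)
    v[:] = J + (v - J) * np.exp(-delta_t / params.tau_m)

    spiked = v > params.threshold
    spikes = spiked.astype(v.dtype)
    if np.any(spiked):
        Js = J[spiked] if J.ndim else J
        # time left in the step after the exact threshold crossing
        remaining = params.tau_m * np.log(
            (Js - params.threshold) / (Js - v[spiked])
        )
        # charge the clock from the interpolated crossing instant: the next
        # step decrements by dt first, so store tau_r + (dt - remaining)
        ref[spiked] = params.tau_r + dt - remaining
        v[spiked] = params.v_reset
    np.clip(v, params.v_floor, None, out=v)
    return state, spikes


def _rate_to_current(rate, params: NeuronParams):
    """Invert the LIF gain function: current at which the rate equals ``rate``."""
    rate = np.asarray(rate, dtype=float)
    z = (1.0 / rate - params.tau_r) / params.tau_m
    return params.threshold / (-np.expm1(-z))


@dataclass
class TuningEnsemble:
    """Gains, biases and normalized encoders of a heterogeneous population.

    ``encoders`` has one row per neuron, each of norm ``1/radius`` so that the
    projection of any point inside the representation ball of radius ``radius``
    lies in [-1, 1].
    """

    radius: float
    gains: np.ndarray
    biases: np.ndarray
    encoders: np.ndarray
    scheme: str = "intercept_maxrate"
    seed: int | None = None
    neuron_params: NeuronParams = field(default_factory=NeuronParams)

    def __post_init__(self) -> None:
        if np.any(self.gains <= 0):
            raise ValueError("gains must be strictly positive")
        norms = np.linalg.norm(self.encoders, axis=1) * self.radius
        if not np.allclose(norms, 1.0, rtol=1e-9):
            raise ValueError("encoder rows must have norm 1/radius")

    @property
    def n_neurons(self) -> int:
        return self.encoders.shape[0]

    @property
    def dim(self) -> int:
        return self.encoders.shape[1]

    def weighted_encoders(self) -> np.ndarray:
        """Full encoding weights e_ia = nu_i * e~_ia."""
        return self.gains[:, None] * self.encoders

    def to_npz(self, path) -> None:
        np.savez(
            path,
            gains=self.gains,
            biases=self.biases,
            encoders=self.encoders,
            radius=self.radius,
            scheme=self.scheme,
            seed=-1 if self.seed is None else self.seed,
        )

    @classmethod
    def from_npz(cls, path) -> "TuningEnsemble":
        with np.load(path, allow_pickle=False) as f:
            seed = int(f["seed"])
            return cls(
                radius=float(f["radius"]),
                gains=f["gains"],
                biases=f["biases"],
                encoders=f["encoders"],
                scheme=str(f["scheme"]),
                seed=None if seed < 0 else seed,
            )


def _uniform_directions(n: int, dim: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal((n, dim))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    # resample degenerate draws (measure zero, but be safe)
    bad = norms[:, 0] < 1e-12
    while np.any(bad):
        v[bad] = rng.standard_normal((int(bad.sum()), dim))
        norms = np.linalg.norm(v, axis=1, keepdims=True)
        bad = norms[:, 0] < 1e-12
    return v / norms


def sample_tuning(
    n: int,
    dim: int,
    radius: float,
    scheme: str = "intercept_maxrate",
    rng: np.random.Generator | None = None,
    *,
    max_rate_range: tuple[float, float] = (200.0, 400.0),
    intercept_range: tuple[float, float] = (-1.0, 1.0),
    fixed_gain: float = 2.0,
    bias_range: tuple[float, float] = (-2.0, 2.0),
    params: NeuronParams = DEFAULT_PARAMS,
    seed: int | None = None,
) -> TuningEnsemble:
    """Sample a heterogeneous tuning ensemble.

    ``intercept_maxrate`` (the default of the original simulator): for each
    neuron draw the normalized projection at which firing starts (intercept)
    uniformly from [-1, 1) and the rate at projection 1 uniformly from
    [200, 400) Hz, then solve gain and bias so that
    ``nu * intercept + b = threshold`` and ``g(nu + b) = max_rate``.

    ``fixed_gain``: gain 2 for every neuron, bias uniform in [-2, 2).
    """
    if n < 1:
        raise ValueError("need at least one neuron")
    if rng is None:
        rng = np.random.default_rng(seed)
    encoders = _uniform_directions(n, dim, rng) / radius
    if scheme == "intercept_maxrate":
        intercepts = rng.uniform(*intercept_range, size=n)
        max_rates = rng.uniform(*max_rate_range, size=n)
        j_max = _rate_to_current(max_rates, params)
        gains = (j_max - params.threshold) / (1.0 - intercepts)
        biases = params.threshold - gains * intercepts
    elif scheme == "fixed_gain":
        gains = np.full(n, float(fixed_gain))
        biases = rng.uniform(*bias_range, size=n)
    else:
        raise ValueError(f"unknown tuning scheme {scheme!r}")
    return TuningEnsemble(
        radius=radius,
        gains=gains,
        biases=biases,
        encoders=encoders,
        scheme=scheme,
        seed=seed,
        neuron_params=params,
    )


def static_rates(
    ensemble: TuningEnsemble,
    point: np.ndarray,
    encoders_override: np.ndarray | None = None,
) -> np.ndarray:
    """Steady-state rates of every neuron for a represented point (or points).

    ``point`` may be a single ``dim``-vector or an array of shape
    ``(n_points, dim)``; returns rates of shape ``(n,)`` or ``(n_points, n)``.
    """
    enc = ensemble.encoders if encoders_override is None else encoders_override
    point = np.asarray(point, dtype=float)
    if point.shape[-1] != enc.shape[1]:
        raise ValueError(
            f"point dimension {point.shape[-1]} != ensemble dim {enc.shape[1]}"
        )
    proj = point @ enc.T
    J = ensemble.gains * proj + ensemble.biases
    return lif_rate(J, ensemble.neuron_params)
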