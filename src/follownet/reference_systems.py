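"""Reference dynamical systems the network learns to emulate.

Five plants are provided, all integrated with forward Euler at the network
step of 1 ms (the spiking network and the plant share the clock):

* ``linear``   — a 2-D decaying oscillator;
* ``vdp``      — the van der Pol relaxation oscillator;
* ``lorenz``   — the chaotic Lorenz system in shifted coordinates
  (x3 = Z - 28 so all observables vary around zero);
* ``ff_nonlinear`` — the linear oscillator driven through a cubic input
  non-linearity (the feedforward weights must learn the transform);
* ``arm``      — a two-link planar arm moving under gravity with viscous
  joint damping, torques applied at shoulder and elbow.

Time derivatives are in 1/s.  For the arm, physical torques/velocities/angles
are mapped to the dimensionless network representation by fixed scalings
(0.02 per N·m, 0.05 per rad/s, 1/2.5 per rad) so each successive integral of
the command occupies a progressively larger fraction of the representation
radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArmParams",
    "ReferenceSpec",
    "linear_derivative",
    "vdp_derivative",
    "lorenz_derivative",
    "ff_nonlinear_derivative",
    "torque_clip",
    "arm_derivative",
    "make_reference",
    "integrate_reference",
]

#: input scaling shared by all non-arm systems: du/dt term is u / 0.02
INPUT_GAIN = 1.0 / 0.02

ARM_TORQUE_SCALE = 0.02     # network units per N·m
ARM_OMEGA_SCALE = 0.05      # network units per rad/s
ARM_ANGLE_SCALE = 1.0 / 2.5  # network units per rad


def linear_derivative(x: np.ndarray, u: np.ndarray) -> np.ndarray:
    x1, x2 = x
    u1, u2 = u
    return np.array([
        u1 * INPUT_GAIN + (-0.2 * x1 - x2) / 0.05,
        u2 * INPUT_GAIN + (x1 - 0.2 * x2) / 0.05,
    ])


def vdp_derivative(x: np.ndarray, u: np.ndarray) -> np.ndarray:
    x1, x2 = x
    u1, u2 = u
    return np.array([
        u1 * INPUT_GAIN + x2 / 0.125,
        u2 * INPUT_GAIN + (2.0 * (1.0 - x1 * x1) * x2 - x1) / 0.125,
    ])


def lorenz_derivative(x: np.ndarray, u: np.ndarray) -> np.ndarray:
    x1, x2, x3 = x
    u1, u2, u3 = u
    return np.array([
        u1 * INPUT_GAIN + 10.0 * (x2 - x1),
        u2 * INPUT_GAIN - x1 * x3 - x2,
        u3 * INPUT_GAIN + x1 * x2 - 8.0 * (x3 + 28.0) / 3.0,
    ])


def ff_nonlinear_derivative(x: np.ndarray, u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    g = 10.0 * ((u / 0.1) ** 3 - u / 0.4)
    x1, x2 = x
    return np.array([
        g[0] + (-0.2 * x1 - x2) / 0.05,
        g[1] + (x1 - 0.2 * x2) / 0.05,
    ])


@dataclass(frozen=True)
class ArmParams:
    """Two-link arm: human-arm parameters (upper arm = link 1)."""

    m1: float = 1.4    # kg
    m2: float = 1.1
    l1: float = 0.3    # m
    l2: float = 0.33
    s1: float = 0.11   # joint-to-CoM distance, m
    s2: float = 0.16
    I1: float = 0.025  # kg m^2
    I2: float = 0.045
    b11: float = 0.05  # damping, kg m^2 / s
    b12: float = 0.025
    b21: float = 0.025
    b22: float = 0.05
    g: float = 9.81    # m / s^2

    def __post_init__(self) -> None:
        for name in ("m1", "m2", "l1", "l2", "s1", "s2", "I1", "I2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _sigma_tilde(theta: np.ndarray) -> np.ndarray:
    """Clipping profile: 0 below pi/2, linear ramp to 1 at 3*pi/4."""
    return np.clip((np.asarray(theta) - np.pi / 2) / (np.pi / 4), 0.0, 1.0)


def torque_clip(u: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Reduce torque that would push a joint past +/-90 degrees.

    Per joint, the applied torque is reduced by ``u * sigma~(theta)`` when the
    torque acts in the direction of the crossed limit; the reduction ramps
    linearly between 90 and 135 degrees, fully cancelling the torque beyond.
    Continuous in ``theta`` and odd under ``(u, theta) -> (-u, -theta)``.
    """
    u = np.asarray(u, dtype=float)
    theta = np.asarray(theta, dtype=float)
    tau = u.copy()
    pos = u > 0
    neg = u < 0
    tau[pos] -= u[pos] * _sigma_tilde(theta[pos])
    tau[neg] -= u[neg] * _sigma_tilde(-theta[neg])
    return tau


def arm_derivative(
    theta: np.ndarray,
    omega: np.ndarray,
    u: np.ndarray,
    params: ArmParams = ArmParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Equations of motion of the two-link arm under gravity.

    ``theta``, ``omega`` are joint angles (rad) and velocities (rad/s);
    ``u`` the commanded torques (N·m), passed through :func:`torque_clip`.
    Returns ``(dtheta/dt, domega/dt)``.
    """
    p = params
    th1, th2 = theta
    om1, om2 = omega
    d1 = p.I1 + p.I2 + p.m2 * p.l1**2
    d2 = p.m2 * p.l1 * p.s2
    d3 = p.I2
    c2 = np.cos(th2)
    M = np.array([
        [d1 + 2 * d2 * c2 + p.m1 * p.s1**2 + p.m2 * p.s2**2,
         d3 + d2 * c2 + p.m2 * p.s2**2],
        [d3 + d2 * c2 + p.m2 * p.s2**2,
         d3 + p.m2 * p.s2**2],
    ])
    C = np.array([
        -om2 * (2 * om1 + om2),
        om1**2,
    ]) * d2 * np.sin(th2)
    B = np.array([[p.b11, p.b12], [p.b21, p.b22]])
    D = np.array([
        (p.m1 * p.s1 + p.m2 * p.l1) * np.sin(th1) + p.m2 * p.s2 * np.sin(th1 + th2),
        p.m2 * p.s2 * np.sin(th1 + th2),
    ])
    tau = torque_clip(u, theta)
    rhs = tau - C - B @ omega - p.g * D
    try:
        domega = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - physical M is PD
        raise FloatingPointError("singular arm inertia matrix") from exc
    return omega.copy(), domega


_SYSTEMS = {
    "linear": dict(dim=2, dim_cmd=2, deriv=linear_derivative, filter_reference=True),
    "vdp": dict(dim=2, dim_cmd=2, deriv=vdp_derivative, filter_reference=True),
    "lorenz": dict(dim=3, dim_cmd=3, deriv=lorenz_derivative, filter_reference=True),
    "ff_nonlinear": dict(dim=2, dim_cmd=2, deriv=ff_nonlinear_derivative,
                         filter_reference=True),
    "arm": dict(dim=4, dim_cmd=2, deriv=None, filter_reference=False),
}


@dataclass
class ReferenceSpec:
    """Which plant to integrate and how its signals map to network units."""

    system: str
    filter_reference: bool = True
    arm_params: ArmParams = field(default_factory=ArmParams)
    x0: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.system not in _SYSTEMS:
            raise ValueError(f"unknown reference system {self.system!r}")

    @property
    def dim(self) -> int:
        return _SYSTEMS[self.system]["dim"]

    @property
    def dim_cmd(self) -> int:
        return _SYSTEMS[self.system]["dim_cmd"]

    def default_x0(self) -> np.ndarray:
        if self.system == "lorenz":
            # shifted-coordinate equilibrium would be (0,0,-28); start at rest
            # in observable coordinates instead
            return np.zeros(3)
        return np.zeros(self.dim)


def make_reference(system: str, **kwargs) -> ReferenceSpec:
    """Reference spec with the shipped defaults (reference filtering off for
    the arm, on elsewhere; pass ``filter_reference=False`` for the unfiltered
    Lorenz variant)."""
    defaults = dict(filter_reference=_SYSTEMS[system]["filter_reference"])
    defaults.update(kwargs)
    return ReferenceSpec(system=system, **defaults)


def integrate_reference(
    spec: ReferenceSpec,
    u_series: np.ndarray,
    dt: float,
    x0: np.ndarray | None = None,
    substeps: int = 1,
) -> np.ndarray:
    """Forward-Euler integrate the reference under a command series.

    ``u_series`` has shape (T, dim_cmd) in *network units*; the returned state
    trajectory (T, dim) is also in network units (for the arm, commands are
    un-scaled into torques before integration and states re-scaled after).
    ``x_ref[t]`` is the state *after* the t-th Euler step, i.e. the state the
    network is asked to predict at tick t.  ``substeps > 1`` integrates at
    ``dt/substeps`` (same samples returned) and serves as the fine-step oracle.
    """
    u_series = np.asarray(u_series, dtype=float)
    if u_series.ndim != 2 or u_series.shape[1] != spec.dim_cmd:
        raise ValueError("u_series must have shape (T, dim_cmd)")
    n_steps = u_series.shape[0]
    h = dt / substeps
    out = np.empty((n_steps, spec.dim))

    if spec.system == "arm":
        if x0 is None:
            theta = np.zeros(2)
            omega = np.zeros(2)
        else:
            theta = np.asarray(x0[:2], float) / ARM_ANGLE_SCALE
            omega = np.asarray(x0[2:], float) / ARM_OMEGA_SCALE
        for t in range(n_steps):
            torque = u_series[t] / ARM_TORQUE_SCALE
            for _ in range(substeps):
                dth, dom = arm_derivative(theta, omega, torque, spec.arm_params)
                theta = theta + h * dth
                omega = omega + h * dom
            if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(omega))):
                raise FloatingPointError(
                    f"non-finite arm state at t={t * dt:.3f} s"
                )
            out[t, :2] = theta * ARM_ANGLE_SCALE
            out[t, 2:] = omega * ARM_OMEGA_SCALE
        return out

    deriv = _SYSTEMS[spec.system]["deriv"]
    x = (spec.default_x0() if x0 is None else np.asarray(x0, dtype=float)).copy()
    # overflow warnings suppressed: divergence is detected and raised below
    with np.errstate(over="ignore", invalid="ignore"):
        for t in range(n_steps):
            u = u_series[t]
            for _ in range(substeps):
                x = x + h * deriv(x, u)
            if not np.all(np.isfinite(x)):
                raise FloatingPointError(
                    f"non-finite reference state at t={t * dt:.3f} s"
                )
            out[t] = x
    return out


def arm_energy(theta: np.ndarray, omega: np.ndarray,
               params: ArmParams = ArmParams()) -> float:
    """Total mechanical energy of the arm (for integrator consistency checks).

    Potential energy is measured from the hanging rest configuration.
    """
    p = params
    th1, th2 = theta
    d1 = p.I1 + p.I2 + p.m2 * p.l1**2
    d2 = p.m2 * p.l1 * p.s2
    d3 = p.I2
    c2 = np.cos(th2)
    M = np.array([
        [d1 + 2 * d2 * c2 + p.m1 * p.s1**2 + p.m2 * p.s2**2,
         d3 + d2 * c2 + p.m2 * p.s2**2],
        [d3 + d2 * c2 + p.m2 * p.s2**2, d3 + p.m2 * p.s2**2],
    ])
    kinetic = 0.5 * omega @ M @ omega
    # heights of the two CoMs relative to hanging rest
    h1 = p.s1 * (1 - np.cos(th1))
    h2 = p.l1 * (1 - np.cos(th1)) + p.s2 * (1 - np.cos(th1 + th2))
    potential = p.g * (p.m1 * h1 + p.m2 * h2)
    return float(kinetic + potential)
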