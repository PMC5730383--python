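"""Readout decoders forming an auto-encoder with the error-feedback encoders.

Before any learning of the feedforward/recurrent weights, the linear readout
``d`` from the recurrent population is solved so that feeding a low-dimensional
vector ``eps`` into the population through the (fixed, random) error encoders
and decoding the resulting static rates returns approximately ``eps`` again.
With the feedback gain ``k`` applied on the encoding side, the loop then
returns ``k * eps`` — the high-gain negative-feedback loop that clamps the
network output to the reference during learning.

The solve is a plain ridge regression on static rates at P points drawn
volume-uniformly from the representation ball, with the regularizer
``lambda = P * (0.1 * max rate)**2`` and P equal to the number of neurons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .lif import TuningEnsemble, static_rates

__all__ = ["DecoderSolve", "sample_ball", "solve_decoders", "roundtrip_check"]


@dataclass
class DecoderSolve:
    """Result of the decoder regression.

    decoders : (dim, n) matrix mapping filtered spike traces to the output
    lambda_reg : ridge coefficient actually used
    n_samples : number of training points P
    sample_radius : radius of the ball the points were drawn from
    """

    decoders: np.ndarray
    lambda_reg: float
    n_samples: int
    sample_radius: float


def sample_ball(
    n: int, dim: int, radius: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` points volume-uniformly from the ``dim``-ball of ``radius``."""
    directions = rng.standard_normal((n, dim))
    norms = np.linalg.norm(directions, axis=1, keepdims=True)
    norms[norms < 1e-12] = 1.0
    radii = radius * rng.uniform(0.0, 1.0, size=(n, 1)) ** (1.0 / dim)
    return directions / norms * radii


def solve_decoders(
    ensemble: TuningEnsemble,
    n_samples: int | None = None,
    rng: np.random.Generator | None = None,
) -> DecoderSolve:
    """Ridge-solve readout decoders that invert the ensemble's encoding.

    Activities are the *static* rates of the gain function (not simulated
    spikes).  The feedback gain ``k`` is not folded into the decoders: they
    target the sample points themselves, and the loop gain is applied on the
    encoding side.
    """
    if rng is None:
        rng = np.random.default_rng()
    P = ensemble.n_neurons if n_samples is None else int(n_samples)
    if P < ensemble.dim:
        raise ValueError("need at least dim samples")
    eps = sample_ball(P, ensemble.dim, ensemble.radius, rng)
    A = static_rates(ensemble, eps)  # (P, N)
    a_max = A.max()
    if a_max <= 0:
        raise ValueError("degenerate tuning: all sampled activities are zero")
    lam = P * (0.1 * a_max) ** 2
    gram = A.T @ A
    gram[np.diag_indices_from(gram)] += lam
    # (N, dim) solution of (A^T A + lam I) d^T = A^T eps
    dT = scipy.linalg.solve(gram, A.T @ eps, assume_a="pos")
    return DecoderSolve(
        decoders=dT.T,
        lambda_reg=float(lam),
        n_samples=P,
        sample_radius=ensemble.radius,
    )


def roundtrip_check(
    ensemble: TuningEnsemble,
    decoders: np.ndarray,
    k: float = 1.0,
    n_test: int = 100,
    rng: np.random.Generator | None = None,
) -> dict:
    """Relative round-trip errors ``|k*decode(rates(eps)) - k*eps| / |eps|``.

    Returns a summary dict with the per-point relative errors, their mean, and
    the absolute decode error at the origin.
    """
    if rng is None:
        rng = np.random.default_rng()
    eps = sample_ball(n_test, ensemble.dim, ensemble.radius, rng)
    rates = static_rates(ensemble, eps)  # (n_test, N)
    decoded = rates @ decoders.T  # targets eps; k scales both sides
    err = np.linalg.norm(k * decoded - k * eps, axis=1)
    denom = k * np.linalg.norm(eps, axis=1)
    rel = err / denom
    origin = np.linalg.norm(
        k * (static_rates(ensemble, np.zeros(ensemble.dim)) @ decoders.T)
    )
    return {
        "relative_errors": rel,
        "mean_relative_error": float(rel.mean()),
        "origin_abs_error": float(origin),
    }
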