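"""Synthesis of 3D arm movements from curvature/torsion specifications.

Given curvature and torsion profiles along the arm, a 3D configuration is
reconstructed by integrating the Frenet-Serret equations

    r' = T,   T' = kappa N,   N' = -kappa T + tau B,   B' = -tau N

along arclength with a fourth-order Runge-Kutta scheme, re-orthonormalizing
the frame after every step.  A behavior is a sequence of such
reconstructions: the time slices of the surfaces rendered from a curvature
unit (optionally coupled with a torsion unit) supply the per-frame
profiles, with a fixed base position and frame.

Because the extracted torsion is unsigned, synthesis interprets torsion
surfaces as positive tau — chirality is fixed right-handed.

A vocabulary of n_C curvature units and n_T torsion units spans
n_C * (n_T + 1) behaviors: every curvature unit alone is a planar
behavior, and every curvature-torsion pairing is a 3D behavior.  (A
torsion unit alone leaves a straight arm straight, so it contributes no
behavior by itself.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decompose import GaussianUnit, evaluate_mixture
from .exceptions import ValidationError
from .geometry import BackboneCurve, MovementSequence

__all__ = [
    "BehaviorVocabulary",
    "frenet_reconstruct",
    "simulate_behavior",
    "count_behaviors",
]


@dataclass
class BehaviorVocabulary:
    """The kinematic-unit vocabulary: centroid Gaussians per quantity."""

    curvature_units: list[GaussianUnit]
    torsion_units: list[GaussianUnit]

    def __post_init__(self) -> None:
        if len(self.curvature_units) < 1:
            raise ValidationError("vocabulary needs at least one curvature unit")

    @property
    def n_C(self) -> int:
        return len(self.curvature_units)

    @property
    def n_T(self) -> int:
        return len(self.torsion_units)


def count_behaviors(vocab: BehaviorVocabulary) -> int:
    """Number of distinct behaviors the vocabulary spans: n_C * (n_T + 1)."""
    return vocab.n_C * (vocab.n_T + 1)


def _check_frame(frame: np.ndarray) -> np.ndarray:
    F = np.asarray(frame, dtype=float).reshape(3, 3)
    if not np.allclose(F @ F.T, np.eye(3), atol=1e-8):
        raise ValidationError("initial (T, N, B) frame must be orthonormal")
    return F


def frenet_reconstruct(
    kappa: np.ndarray,
    tau: np.ndarray | None = None,
    length: float = 1.0,
    origin=(0.0, 0.0, 0.0),
    frame: np.ndarray | None = None,
) -> BackboneCurve:
    """Integrate the Frenet-Serret system into a 3D curve.

    ``kappa`` and ``tau`` are profiles on a uniform arclength grid spanning
    [0, length]; values between nodes are linearly interpolated for the
    Runge-Kutta half steps.  Straight sections (kappa = 0) advance the
    frame by parallel transport, which the system does naturally.  The
    returned curve has len(kappa) points and total chord length within
    0.1% of ``length``.
    """
    kappa = np.asarray(kappa, dtype=float)
    n = kappa.size
    if n < 2:
        raise ValidationError("need at least 2 profile samples")
    tau = np.zeros(n) if tau is None else np.asarray(tau, dtype=float)
    if tau.shape != kappa.shape:
        raise ValidationError("kappa and tau profiles must have equal length")
    if length <= 0:
        raise ValidationError("length must be positive")
    F = np.eye(3) if frame is None else _check_frame(frame)
    T, N, B = F[0].copy(), F[1].copy(), F[2].copy()
    r = np.asarray(origin, dtype=float).copy()

    s_grid = np.linspace(0.0, length, n)
    h = length / (n - 1)

    def coeffs(s: float) -> tuple[float, float]:
        return float(np.interp(s, s_grid, kappa)), float(np.interp(s, s_grid, tau))

    def deriv(state: np.ndarray, s: float) -> np.ndarray:
        rr, TT, NN, BB = state.reshape(4, 3)
        kap, to = coeffs(s)
        return np.concatenate([TT, kap * NN, -kap * TT + to * BB, -to * NN])

    pts = np.empty((n, 3))
    pts[0] = r
    state = np.concatenate([r, T, N, B])
    for i in range(n - 1):
        s = s_grid[i]
        k1 = deriv(state, s)
        k2 = deriv(state + 0.5 * h * k1, s + 0.5 * h)
        k3 = deriv(state + 0.5 * h * k2, s + 0.5 * h)
        k4 = deriv(state + h * k3, s + h)
        state = state + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        r, T, N, B = state.reshape(4, 3)
        # Gram-Schmidt re-orthonormalization, preserving frame handedness
        T = T / np.linalg.norm(T)
        N = N - (N @ T) * T
        N = N / np.linalg.norm(N)
        Bc = np.cross(T, N)
        B = Bc if B @ Bc >= 0 else -Bc
        state = np.concatenate([r, T, N, B])
        pts[i + 1] = r
    return BackboneCurve(pts)


def simulate_behavior(
    curv: GaussianUnit,
    tors: GaussianUnit | None = None,
    n: int = 100,
    length: float = 1.0,
    base_frame: np.ndarray | None = None,
) -> MovementSequence:
    """Render a behavior from a curvature unit (optionally with torsion).

    Both units are evaluated on the [0, 1]^2 grid; each time slice supplies
    kappa(s) and tau(s) profiles that are reconstructed into one frame with
    a common, stationary base position and frame.
    """
    axis = np.linspace(0.0, 1.0, n)
    ksurf = evaluate_mixture([curv], axis, axis, quantity="curvature").values
    tsurf = (
        evaluate_mixture([tors], axis, axis, quantity="torsion").values
        if tors is not None
        else np.zeros((n, n))
    )
    curves = [
        frenet_reconstruct(ksurf[i], tsurf[i], length=length, frame=base_frame)
        for i in range(n)
    ]
    return MovementSequence(curves=curves, times=axis)
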