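"""Discrete differential geometry of sampled 3D backbone curves.

A flexible appendage (the motivating system is the octopus arm, a muscular
hydrostat with no skeleton) is represented per video frame by its virtual
backbone: an ordered list of 3D points from base to tip.  A movement is a
time sequence of such curves.  This module converts raw curve sequences
into a pair of smooth, normalized *kinematic surfaces* — curvature
kappa(s, t) and torsion tau(s, t) on an n x n grid over arm index
s in [0, 1] (0 = base, 1 = tip) and normalized time t in [0, 1] — plus
bend-point and proximal-elongation descriptors.

Curvature at a sample is estimated as the inverse circumradius of the
circle through three successive points,

    kappa(A, B, C) = 4 * sqrt(s (s-a) (s-b) (s-c)) / (a b c),

with a, b, c the pairwise distances and s the semi-perimeter.  Torsion at
the middle of five successive points A..E is the (unsigned) angle between
the osculating-plane normals of triangles ABC and CDE divided by the
distance between B and D.  Both are intrinsic quantities, so the surfaces
are invariant to rigid motion of the input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._splines import smoothing_operator
from .exceptions import (
    DegenerateCurveError,
    DegenerateTriangleError,
    NoBendError,
    ShapeError,
    ValidationError,
)

_log = logging.getLogger(__name__)

#: relative sine-of-angle threshold below which a point triple is treated as
#: collinear; straight arm sections have curvature/torsion 0 in the limit.
COLLINEAR_TOL = 1e-9


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplineConfig:
    """Smoothing-spline tradeoff parameter.

    ``p`` weighs fidelity to the sample points against integrated squared
    second derivative; p = 1 interpolates, p = 0 gives the least-squares
    straight line.  The default 0.99 (on unit-normalized arclength/time
    sites) removes tracking jitter while leaving genuine bends intact.
    """

    p: float = 0.99

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValidationError(f"smoothing parameter p={self.p} outside [0, 1]")


@dataclass
class BackboneCurve:
    """One frame's arm midline: ordered 3D points, base to tip."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ShapeError(f"expected (n, 3) points, got {pts.shape}")
        if pts.shape[0] < 2:
            raise DegenerateCurveError("a curve needs at least 2 points")
        if not np.all(np.isfinite(pts)):
            raise ValidationError("curve contains non-finite coordinates")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise DegenerateCurveError("consecutive curve points must be distinct")
        self.points = pts

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def arclengths(self) -> np.ndarray:
        """Cumulative chord length at each sample, starting at 0."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arclengths[-1])


@dataclass
class MovementSequence:
    """Ordered frames of one movement with normalized time stamps."""

    curves: list[BackboneCurve]
    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if len(self.curves) < 3:
            raise ValidationError("a movement needs at least 3 frames")
        if t.shape != (len(self.curves),):
            raise ShapeError("times must match the number of frames")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("time stamps must be strictly increasing")
        ns = {c.n for c in self.curves}
        if len(ns) != 1:
            raise ShapeError(f"all frames must share n, got counts {sorted(ns)}")
        self.times = t

    @property
    def m(self) -> int:
        return len(self.curves)

    @property
    def n(self) -> int:
        return self.curves[0].n

    def normalized_times(self) -> np.ndarray:
        """Times affinely mapped onto [0, 1]."""
        t = self.times
        return (t - t[0]) / (t[-1] - t[0])


@dataclass
class KinematicSurface:
    """n_t x n_s grid of curvature or torsion values over (s, t)."""

    values: np.ndarray  # rows: time grid, columns: arm-index grid
    quantity: str  # "curvature" | "torsion"
    s_axis: np.ndarray
    t_axis: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        s = np.asarray(self.s_axis, dtype=float)
        t = np.asarray(self.t_axis, dtype=float)
        if self.quantity not in ("curvature", "torsion"):
            raise ValidationError(f"unknown quantity {self.quantity!r}")
        if v.ndim != 2 or v.shape != (t.size, s.size):
            raise ShapeError(
                f"values shape {v.shape} does not match axes ({t.size}, {s.size})"
            )
        if not np.all(np.isfinite(v)):
            raise ValidationError("surface contains non-finite values")
        if v.size and v.min() < -1e-9:
            raise ValidationError("curvature/torsion surfaces must be nonnegative")
        np.clip(v, 0.0, None, out=v)
        self.values, self.s_axis, self.t_axis = v, s, t

    @property
    def cell_area(self) -> float:
        ds = self.s_axis[1] - self.s_axis[0] if self.s_axis.size > 1 else 1.0
        dt = self.t_axis[1] - self.t_axis[0] if self.t_axis.size > 1 else 1.0
        return float(ds * dt)

    @property
    def total_mass(self) -> float:
        """Grid sum times cell area — the surface 'mass' Z."""
        return float(self.values.sum() * self.cell_area)


# ---------------------------------------------------------------------------
# resampling and smoothing
# ---------------------------------------------------------------------------


def resample_uniform(points: np.ndarray, n: int) -> BackboneCurve:
    """Resample a polyline to ``n`` points at equal arclength spacing.

    The first and last input points are preserved exactly; interior points
    come from linear interpolation along the piecewise-linear input.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ShapeError(f"expected (n, 3) points, got {pts.shape}")
    if n < 2:
        raise ValidationError("need n >= 2 output samples")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] == 0.0:
        raise DegenerateCurveError("curve has zero length (fewer than 2 distinct points)")
    targets = np.linspace(0.0, cum[-1], n)
    out = np.column_stack([np.interp(targets, cum, pts[:, i]) for i in range(3)])
    out[0], out[-1] = pts[0], pts[-1]
    return BackboneCurve(out)


def smooth_spline(curve: BackboneCurve, config: SplineConfig) -> BackboneCurve:
    """Smooth a curve coordinate-wise with arclength as the data site.

    Sites are normalized to [0, 1] so the meaning of ``p`` does not depend
    on the physical arm length; the smoothed curve is evaluated at the same
    n sites.
    """
    sites = curve.arclengths / curve.length
    op = smoothing_operator(sites, sites, config.p)
    return BackboneCurve(op @ curve.points)


# ---------------------------------------------------------------------------
# pointwise curvature / torsion estimators
# ---------------------------------------------------------------------------


def circumcircle_curvature(a_pt, b_pt, c_pt) -> float:
    """Inverse circumradius of the circle through three successive points.

    Collinear triples return 0 (straight section); coincident points are a
    degenerate triangle and raise.
    """
    A, B, C = (np.asarray(p, dtype=float) for p in (a_pt, b_pt, c_pt))
    a = float(np.linalg.norm(A - B))
    b = float(np.linalg.norm(B - C))
    c = float(np.linalg.norm(A - C))
    if a == 0.0 or b == 0.0 or c == 0.0:
        raise DegenerateTriangleError("coincident points have no circumcircle")
    s = 0.5 * (a + b + c)
    area_sq = max(s * (s - a) * (s - b) * (s - c), 0.0)
    return 4.0 * np.sqrt(area_sq) / (a * b * c)


def triangle_normal_torsion(a_pt, b_pt, c_pt, d_pt, e_pt) -> float:
    """Torsion at the middle of five successive points.

    The angle between the osculating planes of triangles ABC and CDE,
    divided by the distance between B and D.  The plane angle is unoriented
    (arccos of the absolute normal dot product), so the estimate is
    unsigned and planar curves — including ones with inflections — give 0.
    Degenerate (collinear) triangles return 0 with a logged warning.
    """
    A, B, C, D, E = (np.asarray(p, dtype=float) for p in (a_pt, b_pt, c_pt, d_pt, e_pt))
    n1 = np.cross(B - A, C - A)
    n2 = np.cross(D - C, E - C)
    s1 = np.linalg.norm(B - A) * np.linalg.norm(C - A)
    s2 = np.linalg.norm(D - C) * np.linalg.norm(E - C)
    m1, m2 = np.linalg.norm(n1), np.linalg.norm(n2)
    if m1 <= COLLINEAR_TOL * s1 or m2 <= COLLINEAR_TOL * s2:
        _log.warning("degenerate torsion triangle (straight section); returning 0")
        return 0.0
    d = float(np.linalg.norm(D - B))
    if d == 0.0:
        raise DegenerateTriangleError("coincident window points in torsion estimate")
    cosang = abs(float(n1 @ n2) / (m1 * m2))
    return float(np.arccos(min(cosang, 1.0)) / d)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


def curvature_profile(curve: BackboneCurve) -> np.ndarray:
    """Per-sample curvature, length n.

    Interior values come from a sliding 3-point circumcircle window; the two
    endpoint values replicate the nearest interior value (curvature is
    undefined there but the surfaces must stay n x n).
    """
    P = curve.points
    if curve.n < 3:
        raise DegenerateCurveError("curvature needs at least 3 points")
    A, B, C = P[:-2], P[1:-1], P[2:]
    a = np.linalg.norm(A - B, axis=1)
    b = np.linalg.norm(B - C, axis=1)
    c = np.linalg.norm(A - C, axis=1)
    if np.any(c == 0.0):
        raise DegenerateCurveError("curve folds back onto itself (A == C)")
    s = 0.5 * (a + b + c)
    area_sq = np.clip(s * (s - a) * (s - b) * (s - c), 0.0, None)
    kappa = 4.0 * np.sqrt(area_sq) / (a * b * c)
    return np.concatenate([[kappa[0]], kappa, [kappa[-1]]])


def torsion_profile(curve: BackboneCurve) -> np.ndarray:
    """Per-sample unsigned torsion, length n.

    Interior values use the 5-point two-triangle window; the first and last
    two values replicate the nearest interior value.  Collinear windows
    (straight sections) yield 0.
    """
    P = curve.points
    if curve.n < 7:
        raise DegenerateCurveError("torsion needs at least 7 points")
    A, B, C, D, E = P[:-4], P[1:-3], P[2:-2], P[3:-1], P[4:]
    n1 = np.cross(B - A, C - A)
    n2 = np.cross(D - C, E - C)
    m1 = np.linalg.norm(n1, axis=1)
    m2 = np.linalg.norm(n2, axis=1)
    s1 = np.linalg.norm(B - A, axis=1) * np.linalg.norm(C - A, axis=1)
    s2 = np.linalg.norm(D - C, axis=1) * np.linalg.norm(E - C, axis=1)
    ok = (m1 > COLLINEAR_TOL * s1) & (m2 > COLLINEAR_TOL * s2)
    n_deg = int((~ok).sum())
    if n_deg:
        _log.debug("%d degenerate torsion windows set to 0 (straight sections)", n_deg)
    d = np.linalg.norm(D - B, axis=1)
    if np.any(d == 0.0):
        raise DegenerateCurveError("coincident window points in torsion profile")
    tau = np.zeros(P.shape[0] - 4)
    dots = np.abs(np.einsum("ij,ij->i", n1[ok], n2[ok])) / (m1[ok] * m2[ok])
    tau[ok] = np.arccos(np.minimum(dots, 1.0)) / d[ok]
    return np.concatenate([[tau[0], tau[0]], tau, [tau[-1], tau[-1]]])


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------


def build_surfaces(
    seq: MovementSequence,
    config: SplineConfig | None = None,
    tip_exclude_fraction: float = 0.1,
    n: int | None = None,
) -> tuple[KinematicSurface, KinematicSurface]:
    """Build the (curvature, torsion) surface pair for one movement.

    Per frame: resample to n uniform arclength samples, normalize arm
    length to 1, smooth the coordinates with the spline operator, and
    extract curvature/torsion profiles.  The m x n profile stacks are then
    resampled to n x n along the time axis with the same smoothing-spline
    machinery on the normalized time stamps.  The distal
    ``tip_exclude_fraction`` of arm-index columns — where tracked tips are
    noisy and are analyzed separately — is flat-filled from the last
    retained column.  The result is invariant under rigid motion of the
    input because every step operates on intrinsic quantities or is linear.
    """
    if config is None:
        config = SplineConfig()
    if not 0.0 <= tip_exclude_fraction < 0.5:
        raise ValidationError("tip_exclude_fraction must be in [0, 0.5)")
    n = n or seq.n
    if n < 7:
        raise ValidationError("need n >= 7 samples for torsion")

    kappa_rows = np.empty((seq.m, n))
    tau_rows = np.empty((seq.m, n))
    for i, curve in enumerate(seq.curves):
        # anchor at the base: intrinsic, and keeps coordinates O(1) so the
        # surfaces stay numerically invariant under large translations
        rs = resample_uniform(curve.points - curve.points[0], n)
        unit = BackboneCurve(rs.points / rs.length)  # arm length -> 1
        sm = smooth_spline(unit, config)
        kappa_rows[i] = curvature_profile(sm)
        tau_rows[i] = torsion_profile(sm)

    t_sites = seq.normalized_times()
    t_axis = np.linspace(0.0, 1.0, n)
    s_axis = np.linspace(0.0, 1.0, n)
    time_op = smoothing_operator(t_sites, t_axis, config.p)
    kappa_surf = np.clip(time_op @ kappa_rows, 0.0, None)
    tau_surf = np.clip(time_op @ tau_rows, 0.0, None)

    n_excl = int(round(tip_exclude_fraction * n))
    if n_excl > 0:
        last = n - n_excl - 1
        kappa_surf[:, last + 1 :] = kappa_surf[:, [last]]
        tau_surf[:, last + 1 :] = tau_surf[:, [last]]

    return (
        KinematicSurface(kappa_surf, "curvature", s_axis, t_axis),
        KinematicSurface(tau_surf, "torsion", s_axis, t_axis),
    )


# ---------------------------------------------------------------------------
# bend descriptors
# ---------------------------------------------------------------------------


def bend_point(curve: BackboneCurve, floor: float = 1e-3) -> float:
    """Arm index (in [0, 1]) of the curvature maximum — the bend point.

    Raises :class:`NoBendError` when the profile never exceeds ``floor``
    (effectively straight arm).  Ties break to the most proximal maximum.
    """
    kappa = curvature_profile(curve)
    if kappa.max() <= floor:
        raise NoBendError(f"curvature never exceeds floor {floor}")
    return float(np.argmax(kappa)) / (curve.n - 1)


def elongation_ratio(seq: MovementSequence, floor: float = 1e-3) -> np.ndarray:
    """Per-frame ratio of proximal (base-to-bend) length to total arm length.

    Computed on the unnormalized input curves, so it tracks true elongation
    of the section behind the travelling bend during an extension.
    """
    out = np.empty(seq.m)
    for i, curve in enumerate(seq.curves):
        kappa = curvature_profile(curve)
        if kappa.max() <= floor:
            raise NoBendError(f"frame {i}: curvature never exceeds floor {floor}")
        idx = int(np.argmax(kappa[1:-1])) + 1  # interior max: ratio stays in (0, 1)
        arc = curve.arclengths
        out[i] = arc[idx] / arc[-1]
    return out
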