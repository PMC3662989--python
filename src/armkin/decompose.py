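"""Decomposition of kinematic surfaces into weighted 2D Gaussians.

A curvature or torsion surface z(s, t) is approximated as

    z(s, t) = sum_i w_i * g[mu_i, Sigma_i](s, t),

where g is the bivariate normal density with 2x1 mean mu and 2x2
covariance Sigma, and w_i is the Gaussian's weight in surface-mass units.
Each Gaussian is a candidate kinematic unit: a localized bend or twist
episode on a section of the arm over a time interval.

The fit treats the surface as a mass distribution: every grid cell is a
mass-weighted observation at its (s, t) coordinates with weight
proportional to the cell value, and a Gaussian mixture is estimated by
weighted EM.  Mixture proportions pi_i are then rescaled to
w_i = pi_i * Z, with Z the total surface mass (grid sum times cell area),
so that the evaluated mixture approximates the surface in value units and
mass is conserved: sum_i w_i = Z.

The number of Gaussians is selected by minimizing the Bayesian
Information Criterion

    BIC = -2 L + d log(n_obs),

with L the weighted log-likelihood, d = 6k - 1 free parameters (k weights
constrained to a fixed total, 2k means, 3k covariance entries) and n_obs
the number of grid cells with positive mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import NumericalError, ValidationError
from .geometry import KinematicSurface

_log = logging.getLogger(__name__)

#: floor on covariance eigenvalues, prevents collapse onto single cells
COV_EIG_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GaussianUnit:
    """One 2D Gaussian kinematic primitive: weight, mean (s, t), covariance."""

    w: float
    mu: np.ndarray
    Sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float).reshape(2)
        self.Sigma = np.asarray(self.Sigma, dtype=float).reshape(2, 2)
        if self.w < 0:
            raise ValidationError("unit weight must be nonnegative")
        if not np.allclose(self.Sigma, self.Sigma.T, atol=1e-12):
            raise ValidationError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.Sigma)[0] <= 0:
            raise ValidationError("covariance must be positive definite")


@dataclass(frozen=True)
class UnitFeatures:
    """Interpretable descriptors of a Gaussian unit.

    ``center`` is the (arm index, time) location of the peak; ``shape`` the
    eigenvalue ratio lambda_max / lambda_min (elongation of the ellipse);
    ``size`` sqrt(lambda_max * lambda_min), proportional to the ellipse
    area; ``orientation_deg`` the angle in [0, 90] degrees between the
    major principal axis and the arm-index axis; ``weight`` the mass w.
    """

    center: tuple[float, float]
    shape: float
    size: float
    orientation_deg: float
    weight: float


@dataclass
class SurfaceDecomposition:
    """Result of fitting k Gaussians to one surface."""

    units: list[GaussianUnit]
    total_mass: float
    log_likelihood: float
    bic: float
    n_obs: int
    rmse: float
    converged: bool = True
    n_iter: int = 0
    log_likelihood_path: np.ndarray = field(default_factory=lambda: np.empty(0))
    seed: int | None = None
    bic_by_k: dict[int, float] | None = None

    @property
    def k(self) -> int:
        return len(self.units)


# ---------------------------------------------------------------------------
# mixture evaluation
# ---------------------------------------------------------------------------


def _log_gauss(X: np.ndarray, mu: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    """Log bivariate normal density at rows of X (analytic 2x2 inverse)."""
    a, b, d = Sigma[0, 0], Sigma[0, 1], Sigma[1, 1]
    det = a * d - b * b
    if det <= 0.0 or a <= 0.0:
        raise NumericalError("covariance lost positive definiteness")
    dx = X[:, 0] - mu[0]
    dy = X[:, 1] - mu[1]
    maha = (d * dx * dx - 2.0 * b * dx * dy + a * dy * dy) / det
    return -0.5 * maha - np.log(2.0 * np.pi) - 0.5 * np.log(det)


def evaluate_mixture(
    units: list[GaussianUnit],
    s_axis: np.ndarray | None = None,
    t_axis: np.ndarray | None = None,
    n: int = 100,
    quantity: str = "curvature",
) -> KinematicSurface:
    """Render a weighted Gaussian mixture onto an (s, t) grid.

    Cell-sum times cell area approximates ``sum_i w_i`` whenever the
    Gaussians lie well inside the grid.
    """
    if not units:
        raise ValidationError("cannot evaluate an empty mixture")
    s_axis = np.linspace(0.0, 1.0, n) if s_axis is None else np.asarray(s_axis, float)
    t_axis = np.linspace(0.0, 1.0, n) if t_axis is None else np.asarray(t_axis, float)
    S, T = np.meshgrid(s_axis, t_axis)  # rows: time, cols: arm index
    X = np.column_stack([S.ravel(), T.ravel()])
    vals = np.zeros(X.shape[0])
    for u in units:
        vals += u.w * np.exp(_log_gauss(X, u.mu, u.Sigma))
    return KinematicSurface(vals.reshape(S.shape), quantity, s_axis, t_axis)


def unit_features(unit: GaussianUnit) -> UnitFeatures:
    """Eigen-decompose Sigma into center/shape/size/orientation features."""
    evals, evecs = np.linalg.eigh(unit.Sigma)
    lo, hi = float(evals[0]), float(evals[1])
    if lo <= 0:
        raise ValidationError("covariance must be positive definite")
    if (hi - lo) <= 1e-9 * hi:
        orientation = 0.0  # isotropic: orientation undefined, 0 by convention
    else:
        major = evecs[:, 1]
        orientation = float(np.degrees(np.arccos(min(abs(major[0]), 1.0))))
    return UnitFeatures(
        center=(float(unit.mu[0]), float(unit.mu[1])),
        shape=hi / lo,
        size=float(np.sqrt(hi * lo)),
        orientation_deg=orientation,
        weight=float(unit.w),
    )


# ---------------------------------------------------------------------------
# weighted EM
# ---------------------------------------------------------------------------


def _surface_observations(surface: KinematicSurface):
    """Grid cells as mass-weighted observations (negative noise clipped)."""
    vals = np.clip(surface.values, 0.0, None)
    S, T = np.meshgrid(surface.s_axis, surface.t_axis)
    X = np.column_stack([S.ravel(), T.ravel()])
    v = vals.ravel()
    pos = v > 0.0
    return X[pos], v[pos], vals


def _floor_cov(Sigma: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eigh(Sigma)
    if evals[0] >= COV_EIG_FLOOR:
        return Sigma
    evals = np.maximum(evals, COV_EIG_FLOOR)
    return (evecs * evals) @ evecs.T


def _kmeanspp_init(X, v, k, rng):
    """k-means++ seeding on mass-weighted grid cells."""
    p = v / v.sum()
    idx = [rng.choice(X.shape[0], p=p)]
    for _ in range(1, k):
        d2 = np.min(
            np.sum((X[:, None, :] - X[idx][None, :, :]) ** 2, axis=2), axis=1
        )
        w = v * d2
        if w.sum() <= 0:
            idx.append(rng.choice(X.shape[0], p=p))
        else:
            idx.append(rng.choice(X.shape[0], p=w / w.sum()))
    return X[idx].copy()


def fit_gmm_surface(
    surface: KinematicSurface,
    k: int,
    seed: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> SurfaceDecomposition:
    """Fit ``k`` weighted 2D Gaussians to a surface by weighted EM.

    Cell masses are normalized to sum to n_obs so the log-likelihood
    behaves like that of n_obs effective observations; EM stops when the
    relative log-likelihood change drops below ``tol``.  Deterministic for
    a given ``seed``.
    """
    if k < 1:
        raise ValidationError("need k >= 1 Gaussians")
    X, v, vals = _surface_observations(surface)
    Z = surface.total_mass
    if X.shape[0] == 0 or Z <= 0.0:
        _log.warning("zero-mass surface: returning empty decomposition")
        return SurfaceDecomposition(
            units=[], total_mass=0.0, log_likelihood=float("nan"),
            bic=float("nan"), n_obs=0, rmse=0.0, converged=True, seed=seed,
        )
    n_obs = X.shape[0]
    if k > n_obs:
        raise ValidationError(f"k={k} exceeds the {n_obs} positive grid cells")
    rng = np.random.default_rng(seed)
    v = v * (n_obs / v.sum())  # effective counts summing to n_obs

    mus = _kmeanspp_init(X, v, k, rng)
    vbar = v / v.sum()
    gmean = vbar @ X
    gcov = (X - gmean).T @ ((X - gmean) * vbar[:, None])
    Sigmas = np.array([_floor_cov(gcov / k + COV_EIG_FLOOR * np.eye(2))] * k)
    pis = np.full(k, 1.0 / k)

    path = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logp = np.stack(
            [np.log(pis[i]) + _log_gauss(X, mus[i], Sigmas[i]) for i in range(k)]
        )  # (k, n_obs)
        top = logp.max(axis=0)
        lse = top + np.log(np.exp(logp - top).sum(axis=0))
        ll = float(v @ lse)
        path.append(ll)
        R = np.exp(logp - lse)  # responsibilities
        U = R * v  # (k, n_obs) effective masses
        N = U.sum(axis=1)
        for i in range(k):
            if N[i] <= 1e-10 * v.sum():
                # starved component: reseed at a random mass-weighted cell
                j = rng.choice(n_obs, p=v / v.sum())
                mus[i] = X[j]
                Sigmas[i] = _floor_cov(gcov / k + COV_EIG_FLOOR * np.eye(2))
                pis[i] = 1.0 / n_obs
                continue
            mus[i] = (U[i] @ X) / N[i]
            dev = X - mus[i]
            Sigmas[i] = _floor_cov((dev.T @ (dev * U[i][:, None])) / N[i])
        pis = np.maximum(N, 1e-300)
        pis = pis / pis.sum()
        if np.isfinite(prev) and abs(ll - prev) <= tol * abs(prev):
            converged = True
            break
        prev = ll

    units = [GaussianUnit(float(pis[i] * Z), mus[i], Sigmas[i]) for i in range(k)]
    order = np.argsort([-u.w for u in units])
    units = [units[i] for i in order]

    model = evaluate_mixture(units, surface.s_axis, surface.t_axis).values
    rmse = float(np.sqrt(np.mean((model - vals) ** 2)))
    ll = path[-1]
    d = 6 * k - 1
    bic = -2.0 * ll + d * np.log(n_obs)
    return SurfaceDecomposition(
        units=units, total_mass=Z, log_likelihood=ll, bic=float(bic),
        n_obs=n_obs, rmse=rmse, converged=converged, n_iter=it,
        log_likelihood_path=np.asarray(path), seed=seed,
    )


def select_num_gaussians(
    surface: KinematicSurface,
    k_max: int = 6,
    n_starts: int = 5,
    seed: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> SurfaceDecomposition:
    """Choose the number of Gaussians by minimizing BIC over k = 1..k_max.

    For each k the best of ``n_starts`` seeded EM runs (by likelihood) is
    kept; ties in BIC resolve to the smaller k (the more parsimonious
    model).
    """
    if k_max < 1:
        raise ValidationError("need k_max >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(k_max * n_starts)]
    best: SurfaceDecomposition | None = None
    bic_by_k: dict[int, float] = {}
    for k in range(1, k_max + 1):
        best_k: SurfaceDecomposition | None = None
        for j in range(n_starts):
            dec = fit_gmm_surface(
                surface, k, seed=child_seeds[(k - 1) * n_starts + j],
                tol=tol, max_iter=max_iter,
            )
            if dec.k == 0:
                return dec  # zero-mass surface
            if best_k is None or dec.log_likelihood > best_k.log_likelihood:
                best_k = dec
        assert best_k is not None
        bic_by_k[k] = best_k.bic
        if best is None or best_k.bic < best.bic:
            best = best_k
    assert best is not None
    best.bic_by_k = bic_by_k
    return best
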