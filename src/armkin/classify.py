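"""Classification of movements into prototypes over a shared unit vocabulary.

Once a kinematic-unit vocabulary (centroid Gaussians per quantity) is
fixed, each movement is encoded as the nonnegative weight vector

    w = [{w_i^C}, {w_j^T}]

obtained by nonnegative least squares of its curvature and torsion
surfaces on the frozen centroid basis functions.  Stacking these rows
gives a movements x units weight matrix; k-means on the rows (plain
Euclidean — the weights share units) groups movements whose surfaces are
spanned by similar unit combinations.  Cluster-mean weight patterns are
the *movement prototypes*, and rendering a prototype's weights through the
vocabulary yields its characteristic surface pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .cluster import FeatureConfig, _gap_on_features, _kmeans_features, unit_distance, unit_features
from .decompose import GaussianUnit, _log_gauss, evaluate_mixture
from .exceptions import ShapeError, ValidationError
from .geometry import KinematicSurface
from .synth import BehaviorVocabulary

__all__ = [
    "MovementEncoding",
    "PrototypeSet",
    "encode_movement",
    "pool_encoding",
    "cluster_movements",
    "match_movement",
]


@dataclass
class MovementEncoding:
    """One movement's nonnegative weight vector over the shared units."""

    movement_id: str
    weights: np.ndarray  # concatenated [curvature weights, torsion weights]
    n_curvature: int
    residuals: dict[str, float]  # per-quantity fit rmse

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValidationError("encoding weights must be nonnegative")

    @property
    def curvature_weights(self) -> np.ndarray:
        return self.weights[: self.n_curvature]

    @property
    def torsion_weights(self) -> np.ndarray:
        return self.weights[self.n_curvature :]


@dataclass
class PrototypeSet:
    """Movement sub-groups and their prototype weight patterns/surfaces."""

    assignments: np.ndarray  # sub-group label per movement, 0..k-1
    prototype_weights: np.ndarray  # (k, n_C + n_T)
    prototype_surfaces: list[tuple[KinematicSurface, KinematicSurface]]
    vocabulary: BehaviorVocabulary

    @property
    def k(self) -> int:
        return self.prototype_weights.shape[0]


def _basis_matrix(units: list[GaussianUnit], surface: KinematicSurface) -> np.ndarray:
    S, T = np.meshgrid(surface.s_axis, surface.t_axis)
    X = np.column_stack([S.ravel(), T.ravel()])
    return np.column_stack([np.exp(_log_gauss(X, u.mu, u.Sigma)) for u in units])


def encode_movement(
    surfaces: tuple[KinematicSurface, KinematicSurface],
    vocabulary: BehaviorVocabulary,
    movement_id: str = "",
) -> MovementEncoding:
    """Project a movement's surface pair onto the frozen unit basis.

    Weights are solved per quantity by nonnegative least squares with the
    centroid means/covariances held fixed; the per-surface residual rmse
    reports how much of the movement the vocabulary cannot express.
    """
    curv_surf, tors_surf = surfaces
    if curv_surf.quantity != "curvature" or tors_surf.quantity != "torsion":
        raise ValidationError("expected a (curvature, torsion) surface pair")
    if curv_surf.values.shape != tors_surf.values.shape or not (
        np.array_equal(curv_surf.s_axis, tors_surf.s_axis)
        and np.array_equal(curv_surf.t_axis, tors_surf.t_axis)
    ):
        raise ShapeError("curvature and torsion surfaces must share a grid")

    parts, residuals = [], {}
    for surf, units in (
        (curv_surf, vocabulary.curvature_units),
        (tors_surf, vocabulary.torsion_units),
    ):
        b = surf.values.ravel()
        if not units:
            residuals[surf.quantity] = float(np.sqrt(np.mean(b**2)))
            parts.append(np.empty(0))
            continue
        A = _basis_matrix(units, surf)
        w, rnorm = nnls(A, b)
        parts.append(w)
        residuals[surf.quantity] = float(rnorm / np.sqrt(b.size))
    return MovementEncoding(
        movement_id=movement_id,
        weights=np.concatenate(parts),
        n_curvature=vocabulary.n_C,
        residuals=residuals,
    )


def pool_encoding(
    curvature_units: list[GaussianUnit],
    torsion_units: list[GaussianUnit],
    vocabulary: BehaviorVocabulary,
    config: FeatureConfig | None = None,
    movement_id: str = "",
) -> MovementEncoding:
    """Alternative encoding: pool a movement's own fitted Gaussians' weights
    onto the nearest centroid units instead of refitting by least squares."""
    weights = np.zeros(vocabulary.n_C + vocabulary.n_T)
    for offset, own, cents in (
        (0, curvature_units, vocabulary.curvature_units),
        (vocabulary.n_C, torsion_units, vocabulary.torsion_units),
    ):
        if not cents:
            continue
        cfg = config or FeatureConfig.from_units(list(own) + list(cents))
        if cfg.scales is None:
            cfg = FeatureConfig.from_units(list(own) + list(cents), enabled=cfg.enabled)
        cfeats = [unit_features(c) for c in cents]
        for u in own:
            uf = unit_features(u)
            j = int(np.argmin([unit_distance(uf, cf, cfg) for cf in cfeats]))
            weights[offset + j] += u.w
    return MovementEncoding(
        movement_id=movement_id,
        weights=weights,
        n_curvature=vocabulary.n_C,
        residuals={},
    )


def _render_prototype(
    weights: np.ndarray, vocabulary: BehaviorVocabulary, grid_n: int
) -> tuple[KinematicSurface, KinematicSurface]:
    axis = np.linspace(0.0, 1.0, grid_n)
    curv_units = [
        GaussianUnit(float(w), u.mu, u.Sigma)
        for w, u in zip(weights[: vocabulary.n_C], vocabulary.curvature_units)
    ]
    curv = evaluate_mixture(curv_units, axis, axis, quantity="curvature")
    if vocabulary.n_T:
        tors_units = [
            GaussianUnit(float(w), u.mu, u.Sigma)
            for w, u in zip(weights[vocabulary.n_C :], vocabulary.torsion_units)
        ]
        tors = evaluate_mixture(tors_units, axis, axis, quantity="torsion")
    else:
        tors = KinematicSurface(np.zeros((grid_n, grid_n)), "torsion", axis, axis)
    return curv, tors


def cluster_movements(
    encodings: list[MovementEncoding],
    vocabulary: BehaviorVocabulary,
    k: int | str = "auto",
    seed: int | None = None,
    k_range=range(1, 7),
    B: int = 50,
    n_init: int = 10,
    grid_n: int = 100,
) -> PrototypeSet:
    """Group movements into sub-groups by k-means on their weight vectors.

    With ``k="auto"`` the cluster count is chosen by the gap statistic on
    the weight matrix.  Prototype weights are cluster means; prototype
    surfaces are those weights rendered through the vocabulary.
    """
    if not encodings:
        raise ValidationError("no encodings to cluster")
    dim = vocabulary.n_C + vocabulary.n_T
    if any(e.weights.size != dim for e in encodings):
        raise ShapeError("encoding length does not match the vocabulary")
    X = np.vstack([e.weights for e in encodings])
    blocks = [("weights", slice(0, X.shape[1]))]
    scales = np.asarray([1.0])  # weights are commensurate: plain Euclidean

    if k == "auto":
        ks = [kk for kk in sorted(k_range) if kk <= X.shape[0]]
        gap = _gap_on_features(X, ks, blocks, scales, B=B, seed=seed, n_init=max(2, n_init // 2))
        k = gap.k_star
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise ValidationError(f"invalid cluster count {k!r}")
    if len(encodings) < k:
        raise ValidationError("fewer movements than requested clusters")

    labels, centers, _, _ = _kmeans_features(X, int(k), blocks, scales, seed=seed, n_init=n_init)
    surfaces = [_render_prototype(centers[j], vocabulary, grid_n) for j in range(int(k))]
    return PrototypeSet(
        assignments=np.asarray(labels),
        prototype_weights=centers,
        prototype_surfaces=surfaces,
        vocabulary=vocabulary,
    )


def match_movement(encoding: MovementEncoding, prototypes: PrototypeSet) -> int:
    """Label of the nearest prototype weight pattern (ties -> lowest label)."""
    if prototypes.k < 1:
        raise ValidationError("empty prototype set")
    d = np.linalg.norm(prototypes.prototype_weights - encoding.weights, axis=1)
    return int(np.argmin(d))
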