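"""Clustering of Gaussian kinematic units into a unit vocabulary.

Units pooled across movements (per quantity: curvature or torsion) are
clustered with k-means under a weighted Euclidean distance: for each
enabled Gaussian feature (center, shape, size, orientation, weight) the
Euclidean distance between two units is computed separately, divided by
that feature's sample-wide standard deviation, and the per-feature
distances are combined by their quadrature (root-mean-square) average —
a scaled Euclidean norm on the stacked, normalized feature space.

The number of clusters is chosen with the gap statistic

    Gap(k) = (1/B) sum_b log(W*_kb) - log(W_k),

where W_k is the within-cluster dispersion of the data and W*_kb that of
the b-th of B uniform reference samples drawn over the per-feature
bounding box.  The selected k* is the smallest k at a local maximum of
the Gap curve.  Cluster centroids are mapped back to representative
Gaussian units by element-wise parameter averaging; those centroid units
form the kinematic-unit vocabulary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .decompose import GaussianUnit, UnitFeatures, unit_features
from .exceptions import ValidationError

_log = logging.getLogger(__name__)

FEATURE_ORDER = ("center", "shape", "size", "orientation", "weight")
_FEATURE_DIM = {"center": 2, "shape": 1, "size": 1, "orientation": 1, "weight": 1}

#: feature subset used for the reported clusterings (center location,
#: covariance eigenvalue ratio, and weight)
DEFAULT_FEATURES = ("center", "shape", "weight")
#: alternative subset over the full geometric parameterization
GEOMETRIC_FEATURES = ("center", "shape", "size", "orientation")


# ---------------------------------------------------------------------------
# feature space
# ---------------------------------------------------------------------------


def _feature_row(feat: UnitFeatures, enabled) -> np.ndarray:
    parts = []
    for name in enabled:
        if name == "center":
            parts.extend(feat.center)
        else:
            parts.append(
                {"shape": feat.shape, "size": feat.size,
                 "orientation": feat.orientation_deg, "weight": feat.weight}[name]
            )
    return np.asarray(parts, dtype=float)


@dataclass
class FeatureConfig:
    """Which unit features enter the distance, and their normalization.

    ``scales`` holds one positive scale per enabled feature (for the 2D
    center, the root-mean-square of the two coordinate standard
    deviations); component distances are divided by these so features of
    different units become commensurate before averaging.
    """

    enabled: tuple[str, ...] = DEFAULT_FEATURES
    scales: dict[str, float] | None = None

    def __post_init__(self) -> None:
        bad = [f for f in self.enabled if f not in FEATURE_ORDER]
        if bad:
            raise ValidationError(f"unknown features {bad}")
        if not self.enabled:
            raise ValidationError("at least one feature must be enabled")
        self.enabled = tuple(f for f in FEATURE_ORDER if f in self.enabled)

    @classmethod
    def from_units(cls, units: list[GaussianUnit], enabled=DEFAULT_FEATURES) -> "FeatureConfig":
        """Compute normalization scales as sample standard deviations."""
        cfg = cls(enabled=tuple(enabled))
        feats = [unit_features(u) for u in units]
        scales: dict[str, float] = {}
        for name in cfg.enabled:
            if name == "center":
                xy = np.array([f.center for f in feats])
                s = float(np.sqrt(np.mean(xy.var(axis=0))))
            else:
                col = np.array([_feature_row(f, (name,))[0] for f in feats])
                s = float(col.std())
            if s == 0.0:
                _log.warning("feature %r has zero spread; scale set to 1", name)
                s = 1.0
            scales[name] = s
        cfg.scales = scales
        return cfg

    def blocks(self):
        """(name, column slice) per enabled feature in the stacked matrix."""
        out, start = [], 0
        for name in self.enabled:
            d = _FEATURE_DIM[name]
            out.append((name, slice(start, start + d)))
            start += d
        return out

    def scale_vector(self) -> np.ndarray:
        if self.scales is None:
            raise ValidationError("normalization scales missing; use from_units()")
        return np.asarray([self.scales[name] for name in self.enabled], dtype=float)


def feature_matrix(units: list[GaussianUnit], config: FeatureConfig) -> np.ndarray:
    return np.vstack([_feature_row(unit_features(u), config.enabled) for u in units])


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def component_distances(u1: UnitFeatures, u2: UnitFeatures, config: FeatureConfig) -> np.ndarray:
    """Per-feature normalized distances between two units (one value each)."""
    scales = config.scale_vector()
    x1 = _feature_row(u1, config.enabled)
    x2 = _feature_row(u2, config.enabled)
    out = np.empty(len(config.enabled))
    for i, (name, sl) in enumerate(config.blocks()):
        out[i] = np.linalg.norm(x1[sl] - x2[sl]) / scales[i]
    return out


def unit_distance(u1: UnitFeatures, u2: UnitFeatures, config: FeatureConfig) -> float:
    """The weighted Euclidean clustering metric: the quadrature (root mean
    square) average of the normalized per-feature distances.

    Combining the component distances in quadrature makes the metric a
    scaled Euclidean norm on the stacked feature space, so the k-means
    mean-centroid update is exact and within-cluster dispersion separates
    across features (which the gap statistic relies on)."""
    return float(np.sqrt(np.mean(component_distances(u1, u2, config) ** 2)))


def _distance_matrix(X: np.ndarray, C: np.ndarray, blocks, scales: np.ndarray) -> np.ndarray:
    """Pairwise distances (rows of X) x (rows of C) under the block metric."""
    D2 = np.zeros((X.shape[0], C.shape[0]))
    for i, (_, sl) in enumerate(blocks):
        diff = X[:, None, sl] - C[None, :, sl]
        D2 += np.einsum("nkd,nkd->nk", diff, diff) / scales[i] ** 2
    return np.sqrt(D2 / len(blocks))


# ---------------------------------------------------------------------------
# k-means under the block metric
# ---------------------------------------------------------------------------


def _kmeanspp_seed(X, k, blocks, scales, rng):
    idx = [int(rng.integers(X.shape[0]))]
    for _ in range(1, k):
        d = _distance_matrix(X, X[idx], blocks, scales).min(axis=1)
        w = d**2
        if w.sum() <= 0:
            idx.append(int(rng.integers(X.shape[0])))
        else:
            idx.append(int(rng.choice(X.shape[0], p=w / w.sum())))
    return X[idx].copy()


def _objective(X, labels, C, blocks, scales) -> float:
    """Summed squared point-to-centroid distances (the k-means objective;
    squaring is also what makes the gap-statistic reference comparison
    discriminate beyond the true cluster count)."""
    D = _distance_matrix(X, C, blocks, scales)
    return float((D[np.arange(X.shape[0]), labels] ** 2).sum())


def _kmeans_once(X, k, blocks, scales, rng, max_iter=100):
    """One seeded run: batch (Lloyd) phase then single-point online phase.

    The reported objective path is non-increasing by construction: centroid
    updates or point moves are only accepted when they do not increase the
    summed point-to-centroid distance.
    """
    n = X.shape[0]
    C = _kmeanspp_seed(X, k, blocks, scales, rng)
    D = _distance_matrix(X, C, blocks, scales)
    labels = D.argmin(axis=1)
    obj = float((D[np.arange(n), labels] ** 2).sum())
    path = [obj]

    # phase 1: batch updates
    for _ in range(max_iter):
        newC = C.copy()
        for j in range(k):
            members = labels == j
            if not members.any():
                far = int(_distance_matrix(X, C, blocks, scales)[np.arange(n), labels].argmax())
                _log.debug("empty cluster %d reseeded at farthest point", j)
                newC[j] = X[far]
            else:
                newC[j] = X[members].mean(axis=0)
        D = _distance_matrix(X, newC, blocks, scales)
        new_labels = D.argmin(axis=1)
        new_obj = float((D[np.arange(n), new_labels] ** 2).sum())
        if new_obj > obj - 1e-12:
            break  # mean update no longer helps under the block metric
        C, labels, obj = newC, new_labels, new_obj
        path.append(obj)

    # phase 2: single-point reassignment passes
    for _ in range(50):
        moved = False
        for i in range(n):
            cur = labels[i]
            if (labels == cur).sum() == 1:
                continue  # moving the sole member would empty the cluster
            d_i = _distance_matrix(X[i : i + 1], C, blocks, scales)[0]
            cand = int(d_i.argmin())
            if cand == cur:
                continue
            trial = labels.copy()
            trial[i] = cand
            trialC = C.copy()
            for j in (cur, cand):
                trialC[j] = X[trial == j].mean(axis=0)
            new_obj = _objective(X, trial, trialC, blocks, scales)
            if new_obj < obj - 1e-12:
                labels, C, obj = trial, trialC, new_obj
                path.append(obj)
                moved = True
        if not moved:
            break
    return labels, C, obj, np.asarray(path)


def _kmeans_features(X, k, blocks, scales, seed=None, n_init=10):
    """Best of ``n_init`` seeded runs on a plain feature matrix."""
    if X.shape[0] < k:
        raise ValidationError(f"cannot form {k} clusters from {X.shape[0]} points")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        res = _kmeans_once(X, k, blocks, scales, rng)
        if best is None or res[2] < best[2]:
            best = res
    return best  # labels, centers, objective, path


@dataclass
class UnitClustering:
    """k-means result over Gaussian units."""

    assignments: np.ndarray  # label per unit, 0..k-1
    centroids: list[GaussianUnit]
    centroid_features: list[UnitFeatures]
    within_dispersion: float  # W_k: summed squared point-to-centroid distance
    k: int
    objective_path: np.ndarray = field(default_factory=lambda: np.empty(0))


def cluster_centroid_unit(members: list[GaussianUnit]) -> GaussianUnit:
    """Representative Gaussian of a cluster: element-wise parameter mean.

    A convex combination of SPD covariance matrices is SPD, so the result
    is a valid unit.
    """
    if not members:
        raise ValidationError("cannot average an empty cluster")
    w = float(np.mean([m.w for m in members]))
    mu = np.mean([m.mu for m in members], axis=0)
    Sigma = np.mean([m.Sigma for m in members], axis=0)
    return GaussianUnit(w, mu, Sigma)


def _medoid_unit(members: list[GaussianUnit], config: FeatureConfig) -> GaussianUnit:
    feats = [unit_features(m) for m in members]
    D = np.array([[unit_distance(a, b, config) for b in feats] for a in feats])
    return members[int(D.sum(axis=1).argmin())]


def kmeans_units(
    units: list[GaussianUnit],
    k: int,
    config: FeatureConfig | None = None,
    seed: int | None = None,
    n_init: int = 10,
    centroid_mode: str = "mean",
) -> UnitClustering:
    """Cluster units with k-means under the weighted per-feature distance.

    ``centroid_mode`` selects how clusters map back to representative
    Gaussians: "mean" (parameter averaging) or "medoid".
    """
    if config is None:
        config = FeatureConfig.from_units(units)
    elif config.scales is None:
        config = FeatureConfig.from_units(units, enabled=config.enabled)
    X = feature_matrix(units, config)
    labels, _, obj, path = _kmeans_features(
        X, k, config.blocks(), config.scale_vector(), seed=seed, n_init=n_init
    )
    centroids = []
    for j in range(k):
        members = [u for u, lab in zip(units, labels) if lab == j]
        if centroid_mode == "mean":
            centroids.append(cluster_centroid_unit(members))
        elif centroid_mode == "medoid":
            centroids.append(_medoid_unit(members, config))
        else:
            raise ValidationError(f"unknown centroid_mode {centroid_mode!r}")
    return UnitClustering(
        assignments=np.asarray(labels),
        centroids=centroids,
        centroid_features=[unit_features(c) for c in centroids],
        within_dispersion=obj,
        k=k,
        objective_path=path,
    )


# ---------------------------------------------------------------------------
# gap statistic
# ---------------------------------------------------------------------------


@dataclass
class GapResult:
    k_range: list[int]
    gap: np.ndarray
    W_k: np.ndarray
    reference_W: np.ndarray  # (B, |k_range|)
    B: int
    k_star: int


def gap_statistic(
    units: list[GaussianUnit],
    k_range=range(1, 7),
    config: FeatureConfig | None = None,
    B: int = 50,
    seed: int | None = None,
    n_init: int = 5,
) -> GapResult:
    """Select the number of unit clusters with the gap statistic.

    Reference sets are drawn uniformly over the per-feature min/max box of
    the data (in raw feature space) and clustered with the same metric and
    normalization scales.  ``k_star`` is the smallest k whose Gap value is
    a local maximum (one-sided at the range endpoints).
    """
    ks = sorted(k_range)
    if not ks or ks[0] < 1:
        raise ValidationError("k_range must start at 1 or above")
    if B < 1:
        raise ValidationError("need at least one reference set")
    if config is None:
        config = FeatureConfig.from_units(units)
    elif config.scales is None:
        config = FeatureConfig.from_units(units, enabled=config.enabled)
    X = feature_matrix(units, config)
    return _gap_on_features(X, ks, config.blocks(), config.scale_vector(), B, seed, n_init)


def _gap_on_features(X, ks, blocks, scales, B, seed, n_init) -> GapResult:
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = hi - lo
    degenerate = span == 0.0
    if degenerate.any():
        _log.warning("%d degenerate feature columns (zero range) held constant "
                     "in the reference distribution", int(degenerate.sum()))

    W_k = np.empty(len(ks))
    ref_W = np.empty((B, len(ks)))
    for j, k in enumerate(ks):
        W_k[j] = _kmeans_features(
            X, k, blocks, scales, seed=int(rng.integers(2**31)), n_init=n_init
        )[2]
    for b in range(B):
        Xb = lo + span * rng.random(X.shape)
        for j, k in enumerate(ks):
            ref_W[b, j] = _kmeans_features(
                Xb, k, blocks, scales, seed=int(rng.integers(2**31)), n_init=n_init
            )[2]

    eps = 1e-300
    gap = np.log(np.maximum(ref_W, eps)).mean(axis=0) - np.log(np.maximum(W_k, eps))

    k_star = ks[-1]
    for j, k in enumerate(ks):
        left_ok = j == 0 or gap[j] >= gap[j - 1]
        right_ok = j == len(ks) - 1 or gap[j] >= gap[j + 1]
        if left_ok and right_ok:
            k_star = k
            break
    return GapResult(
        k_range=list(ks), gap=gap, W_k=W_k, reference_W=ref_W, B=B, k_star=k_star
    )
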