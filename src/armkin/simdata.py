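"""Synthetic movement generator with planted Gaussian structure.

Real octopus-arm data show curvature and torsion varying smoothly along
the arm and gradually in time, which is exactly what sums of 2D Gaussians
on the (arm index, time) plane produce.  This module plants known Gaussian
units, renders curvature/torsion surfaces (optionally with clipped
Gaussian noise), and integrates each time slice into a 3D backbone curve,
so every pipeline stage — surface extraction, mixture decomposition, unit
clustering, movement classification — can be scored against known ground
truth without any recorded data.

Defaults follow the scale of tracked arm recordings: n = 100 samples per
curve, 60 frames per movement, unit arm length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decompose import GaussianUnit, evaluate_mixture
from .exceptions import ValidationError
from .geometry import BackboneCurve, KinematicSurface, MovementSequence
from .synth import BehaviorVocabulary, frenet_reconstruct

__all__ = [
    "SimConfig",
    "gen_surface",
    "gen_movement",
    "gen_classification_set",
    "fixtures",
    "four_gaussian_units",
    "extension_vocabulary",
    "extension_weight_patterns",
]


@dataclass
class SimConfig:
    """Conditions for one synthetic movement.

    ``noise_sd`` is the standard deviation of additive surface noise in
    curvature/torsion value units (applied before clipping at 0);
    ``point_jitter_sd`` optionally adds 3D jitter to the reconstructed
    points to stress the spline smoothing.
    """

    curvature_units: list[GaussianUnit] = field(default_factory=list)
    torsion_units: list[GaussianUnit] = field(default_factory=list)
    n: int = 100
    m: int = 60
    noise_sd: float = 0.0
    point_jitter_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.point_jitter_sd < 0:
            raise ValidationError("noise levels must be nonnegative")
        if not self.curvature_units:
            raise ValidationError("need at least one planted curvature unit")


def gen_surface(
    units: list[GaussianUnit],
    n: int = 100,
    noise_sd: float = 0.0,
    seed: int | None = None,
    quantity: str = "curvature",
    s_axis: np.ndarray | None = None,
    t_axis: np.ndarray | None = None,
) -> KinematicSurface:
    """Evaluate planted units on a grid and add seeded, clipped noise."""
    surf = evaluate_mixture(units, s_axis, t_axis, n=n, quantity=quantity)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noisy = surf.values + rng.normal(0.0, noise_sd, surf.values.shape)
        surf = KinematicSurface(
            np.clip(noisy, 0.0, None), quantity, surf.s_axis, surf.t_axis
        )
    return surf


def gen_movement(config: SimConfig) -> tuple[MovementSequence, dict]:
    """Synthesize one movement from planted units.

    Returns the 3D curve sequence plus ground truth: the planted units and
    the noiseless n x n surfaces for recovery scoring.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    s_axis = np.linspace(0.0, 1.0, config.n)
    t_axis = np.linspace(0.0, 1.0, config.m)

    ksurf = gen_surface(
        config.curvature_units, noise_sd=config.noise_sd, seed=seeds[0],
        quantity="curvature", s_axis=s_axis, t_axis=t_axis,
    )
    if config.torsion_units:
        tsurf = gen_surface(
            config.torsion_units, noise_sd=config.noise_sd, seed=seeds[1],
            quantity="torsion", s_axis=s_axis, t_axis=t_axis,
        )
        tvals = tsurf.values
    else:
        tvals = np.zeros((config.m, config.n))

    rng = np.random.default_rng(seeds[2])
    curves = []
    for i in range(config.m):
        curve = frenet_reconstruct(ksurf.values[i], tvals[i], length=1.0)
        pts = curve.points
        if config.point_jitter_sd > 0:
            pts = pts + rng.normal(0.0, config.point_jitter_sd, pts.shape)
        curves.append(BackboneCurve(pts))
    seq = MovementSequence(curves=curves, times=t_axis)

    truth = {
        "curvature_units": config.curvature_units,
        "torsion_units": config.torsion_units,
        "curvature_surface": evaluate_mixture(
            config.curvature_units, n=config.n, quantity="curvature"
        ),
        "torsion_surface": (
            evaluate_mixture(config.torsion_units, n=config.n, quantity="torsion")
            if config.torsion_units
            else None
        ),
    }
    return seq, truth


# ---------------------------------------------------------------------------
# planted structures
# ---------------------------------------------------------------------------


def four_gaussian_units() -> list[GaussianUnit]:
    """Four well-separated units resembling an extension curvature surface:
    a proximal fixed bend, two travelling-bend episodes, and a distal
    late-time episode.  Pairwise center separations exceed 6 sigma."""
    return [
        GaussianUnit(1.2, (0.45, 0.15), [[0.0040, 0.0010], [0.0010, 0.0060]]),
        GaussianUnit(0.9, (0.70, 0.50), [[0.0050, 0.0015], [0.0015, 0.0045]]),
        GaussianUnit(0.7, (0.15, 0.50), [[0.0035, -0.0008], [-0.0008, 0.0055]]),
        GaussianUnit(0.5, (0.75, 0.85), [[0.0045, 0.0000], [0.0000, 0.0040]]),
    ]


#: per-cluster (center_s, center_t, weight, base eigenvalue, shape ratio)
#: templates for planted unit clusters; separations exceed 6 within-cluster
#: standard deviations in normalized feature space
_UNIT_CLUSTER_TEMPLATES = [
    (0.20, 0.20, 0.5, 0.0030, 1.5),
    (0.70, 0.30, 1.5, 0.0020, 3.0),
    (0.45, 0.80, 1.0, 0.0025, 4.5),
    (0.15, 0.65, 2.2, 0.0035, 2.2),
]


def gen_unit_clusters(
    k: int = 3, n_per: int = 20, seed: int | None = None
) -> tuple[list[GaussianUnit], np.ndarray]:
    """Plant ``k`` well-separated clusters of Gaussian units in feature space.

    Clusters differ in center location, weight and covariance shape ratio;
    within-cluster noise is kept comparable across clusters and features
    (center sd 0.012, weight sd 0.03, additive shape-ratio sd 0.05), so the
    separation-to-spread ratio stays above 6 for every enabled feature.
    Returns the shuffled-free unit list and the planted labels.
    """
    if not 1 <= k <= len(_UNIT_CLUSTER_TEMPLATES):
        raise ValidationError(f"k must be in 1..{len(_UNIT_CLUSTER_TEMPLATES)}")
    rng = np.random.default_rng(seed)
    units, labels = [], []
    for c in range(k):
        cs, ct, w, lam0, ratio = _UNIT_CLUSTER_TEMPLATES[c]
        for _ in range(n_per):
            mu = np.array([cs, ct]) + rng.normal(0.0, 0.012, 2)
            r = max(ratio + rng.normal(0.0, 0.05), 1.0)
            lam = lam0 * (1.0 + rng.normal(0.0, 0.02))
            units.append(
                GaussianUnit(max(w + rng.normal(0.0, 0.03), 0.01), mu,
                             np.diag([lam, lam * r]))
            )
            labels.append(c)
    return units, np.asarray(labels)


def extension_vocabulary() -> BehaviorVocabulary:
    """Representative extension-movement vocabulary: three curvature and
    three torsion centroid units at realistic (arm index, time) positions
    (a proximal fixed unit plus two travelling-bend units, and early/mid/
    late torsion episodes)."""
    curv = [
        GaussianUnit(1.0, (0.4627, 0.1574), [[0.0060, 0.0020], [0.0020, 0.0080]]),
        GaussianUnit(1.0, (0.6647, 0.4502), [[0.0070, 0.0025], [0.0025, 0.0065]]),
        GaussianUnit(1.0, (0.1355, 0.4543), [[0.0045, 0.0005], [0.0005, 0.0090]]),
    ]
    tors = [
        GaussianUnit(1.0, (0.2687, 0.2463), [[0.0055, 0.0010], [0.0010, 0.0070]]),
        GaussianUnit(1.0, (0.6245, 0.3288), [[0.0065, 0.0015], [0.0015, 0.0060]]),
        GaussianUnit(1.0, (0.4061, 0.7207), [[0.0050, -0.0010], [-0.0010, 0.0075]]),
    ]
    return BehaviorVocabulary(curvature_units=curv, torsion_units=tors)


def extension_weight_patterns() -> np.ndarray:
    """Three prototype weight patterns over the extension vocabulary
    (rows: prototypes; columns: 3 curvature then 3 torsion units)."""
    return np.array(
        [
            [1.0, 0.3, 0.6, 0.5, 0.2, 0.4],
            [0.3, 1.2, 0.2, 0.1, 0.8, 0.2],
            [0.8, 0.9, 1.0, 0.6, 0.5, 0.9],
        ]
    )


def gen_classification_set(
    vocab: BehaviorVocabulary | None = None,
    patterns: np.ndarray | None = None,
    per_pattern: int = 10,
    noise_frac: float = 0.1,
    weight_jitter_sd: float = 0.05,
    n: int = 100,
    seed: int | None = None,
):
    """Surface pairs for movements drawn from prototype weight patterns.

    Movements of one sub-group share a *similar*, not identical, unit
    combination: each movement's weight vector is its pattern plus
    isotropic Gaussian jitter (sd ``weight_jitter_sd``, clipped at 0).
    Its surfaces are the resulting weighted unit mixture plus clipped
    Gaussian observation noise with sd = ``noise_frac`` times the
    movement's noiseless surface peak.  Returns (surface_pairs, labels,
    truth) with the per-movement true weights in ``truth``.
    """
    vocab = vocab or extension_vocabulary()
    patterns = extension_weight_patterns() if patterns is None else np.asarray(patterns, float)
    if patterns.shape[1] != vocab.n_C + vocab.n_T:
        raise ValidationError("pattern length does not match the vocabulary")
    rng = np.random.default_rng(seed)
    axis = np.linspace(0.0, 1.0, n)
    pairs, labels, true_weights = [], [], []
    for p_idx in range(patterns.shape[0]):
        for _ in range(per_pattern):
            w = np.clip(
                patterns[p_idx] + rng.normal(0.0, weight_jitter_sd, patterns.shape[1]),
                0.0, None,
            )
            curv_units = [
                GaussianUnit(float(wi), u.mu, u.Sigma)
                for wi, u in zip(w[: vocab.n_C], vocab.curvature_units)
                if wi > 0
            ]
            tors_units = [
                GaussianUnit(float(wi), u.mu, u.Sigma)
                for wi, u in zip(w[vocab.n_C :], vocab.torsion_units)
                if wi > 0
            ]
            s1, s2 = (int(x) for x in rng.integers(2**31, size=2))
            kpeak = evaluate_mixture(curv_units, n=n).values.max()
            curv = gen_surface(curv_units, n=n, noise_sd=noise_frac * kpeak, seed=s1)
            if tors_units:
                tpeak = evaluate_mixture(tors_units, n=n, quantity="torsion").values.max()
                tors = gen_surface(
                    tors_units, n=n, noise_sd=noise_frac * tpeak, seed=s2,
                    quantity="torsion",
                )
            else:
                tors = KinematicSurface(np.zeros((n, n)), "torsion", axis, axis)
            pairs.append((curv, tors))
            labels.append(p_idx)
            true_weights.append(w)
    truth = {
        "vocabulary": vocab,
        "patterns": patterns,
        "per_pattern": per_pattern,
        "weights": np.vstack(true_weights),
    }
    return pairs, np.asarray(labels), truth


# ---------------------------------------------------------------------------
# analytic fixtures
# ---------------------------------------------------------------------------


def _helix_points(a: float, b: float, theta_max: float, n: int) -> np.ndarray:
    th = np.linspace(0.0, theta_max, n)
    return np.column_stack([a * np.cos(th), a * np.sin(th), b * th])


def fixtures() -> dict:
    """Named analytic objects with closed-form curvature/torsion.

    - "line": straight segment (kappa = tau = 0)
    - "circle_r1", "circle_r2": circular arcs (kappa = 1, 0.5; tau = 0)
    - "helix": a=1, b=0.5 over one turn (kappa = 0.8, tau = 0.4)
    - "s_curve": planar sine with an inflection (tau = 0)
    - "helix_sequence": 15-frame sequence with drifting pitch, torsion
      well-conditioned everywhere (for invariance checks)
    - "extension_units" / "extension_surface": the planted 4-Gaussian
      curvature structure of an extension-like movement
    Deterministic: identical on every call.
    """
    n = 100
    th_circle = np.linspace(0.0, 1.5 * np.pi, n)
    th_semi = np.linspace(0.0, np.pi, n)
    line = np.column_stack([np.linspace(0.0, 1.0, n), np.zeros(n), np.zeros(n)])
    s_x = np.linspace(0.0, 2.0, n)
    s_curve = np.column_stack([s_x, 0.3 * np.sin(np.pi * s_x), np.zeros(n)])

    seq_curves = []
    m = 15
    for b in np.linspace(0.3, 0.7, m):
        seq_curves.append(BackboneCurve(_helix_points(1.0, b, 2.0 * np.pi, n)))
    units = four_gaussian_units()
    return {
        "line": BackboneCurve(line),
        "circle_r1": BackboneCurve(
            np.column_stack([np.cos(th_circle), np.sin(th_circle), np.zeros(n)])
        ),
        "circle_r2": BackboneCurve(
            np.column_stack([2 * np.cos(th_semi), 2 * np.sin(th_semi), np.zeros(n)])
        ),
        "helix": BackboneCurve(_helix_points(1.0, 0.5, 2.0 * np.pi, n)),
        "s_curve": BackboneCurve(s_curve),
        "helix_sequence": MovementSequence(
            curves=seq_curves, times=np.linspace(0.0, 1.0, m)
        ),
        "extension_units": units,
        "extension_surface": evaluate_mixture(units, n=n, quantity="curvature"),
    }
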