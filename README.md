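# armkin

Kinematic decomposition of flexible-appendage movements into motion
primitives.

Appendages without a skeleton — octopus arms, tongues, trunks — bend and
twist anywhere along their length, so their movements cannot be described
by joint angles. `armkin` is for researchers in neuroethology, motor
control, and soft robotics who have tracked such an appendage as a 3D
midline curve per frame and want to know whether its movement repertoire
is built from a small vocabulary of elementary kinematic units.

## The method

A movement (m frames of n backbone points) is represented by a pair of
**kinematic surfaces** on the unit square — curvature κ(s, t) and
torsion τ(s, t) over arm index s ∈ [0, 1] (base → tip) and normalized
time t ∈ [0, 1]. κ is estimated from the circumcircle of three successive
samples, κ = 4√(s(s−a)(s−b)(s−c))/(abc); τ from the angle between the
osculating planes of successive sample triangles divided by the
separation of their middle points. Both are intrinsic, so the surfaces
are invariant to rigid motion of the arm.

Each surface is decomposed into a weighted sum of 2D Gaussians,

  z(s, t) = Σᵢ wᵢ · g[μᵢ, Σᵢ](s, t),

by weighted EM over mass-weighted grid cells, with the number of
Gaussians chosen by BIC = −2L + d·log(n_obs). Each Gaussian is a
**kinematic unit**: a bend or twist episode on an arm section over a time
interval, described by its center, shape (eigenvalue ratio of Σ), size,
orientation, and weight. Units pooled across movements are clustered
(k-means under a feature-normalized weighted Euclidean distance; cluster
count by the gap statistic) and the cluster centroids form the unit
vocabulary. Every movement is then encoded as a nonnegative weight vector
over the vocabulary, movements with similar weight patterns cluster into
**prototypes**, and any unit combination can be synthesized back into a
3D movement by integrating the Frenet–Serret equations per time slice.
A vocabulary of n_C curvature and n_T torsion units spans n_C·(n_T + 1)
behaviors.

See `docs/methods.md` for assumptions, parameter defaults, and numerical
choices.

## Worked example

Plant a single travelling bend — a curvature ridge moving base → tip —
synthesize the 3D movement, and recover the unit from the extracted
surface:

```python
import numpy as np
from armkin import (GaussianUnit, build_surfaces, select_num_gaussians,
                    unit_features, bend_point)
from armkin.simdata import SimConfig, gen_movement

bend = GaussianUnit(4.0, (0.5, 0.5), [[0.02, 0.018], [0.018, 0.02]])
seq, truth = gen_movement(SimConfig(curvature_units=[bend], n=100, m=60, seed=0))
print(f"movement: {seq.m} frames x {seq.n} points")

curv, tors = build_surfaces(seq)
print(f"curvature surface: {curv.values.shape}, peak {curv.values.max():.3f}, "
      f"mass {curv.total_mass:.3f}")
print(f"torsion surface peak: {tors.values.max():.2e}  (planar movement)")

dec = select_num_gaussians(curv, k_max=3, n_starts=5, seed=0)
print(f"BIC selects k = {dec.k} (BIC by k: "
      + ", ".join(f"{k}: {v:.0f}" for k, v in dec.bic_by_k.items()) + ")")
u, f = dec.units[0], unit_features(dec.units[0])
print(f"unit: w = {u.w:.3f}, center = ({f.center[0]:.3f}, {f.center[1]:.3f}), "
      f"shape = {f.shape:.2f}, orientation = {f.orientation_deg:.1f} deg")
bends = [bend_point(c) for c in seq.curves[10:50]]
print(f"bend point drifts {bends[0]:.2f} -> {bends[-1]:.2f} along the arm")
```

Output:

```
movement: 60 frames x 100 points
curvature surface: (100, 100), peak 73.415, mass 3.991
torsion surface peak: 0.00e+00  (planar movement)
BIC selects k = 1 (BIC by k: 1: -30302, 2: -30296, 3: -30269)
unit: w = 3.991, center = (0.502, 0.501), shape = 19.20, orientation = 44.7 deg
bend point drifts 0.20 -> 0.80 along the arm
```

The planted weight (4.0), center (0.5, 0.5), covariance shape
(eigenvalue ratio 19) and 45° orientation — the signature of a bend
travelling tip-ward at constant speed — are recovered from the 3D curves,
BIC correctly refuses extra Gaussians, and the torsion surface is zero
because a curvature unit alone defines a planar behavior.

## Command-line pipeline

The same stages are available as subcommands operating on plain-text
files (curve tables, surface matrices with JSON sidecars, JSON records):

```sh
armkin simulate -o curves.tsv --per-pattern 5 --seed 1
armkin surfaces curves.tsv -o surfaces/
armkin decompose surfaces/proto0_rep0_curvature.tsv -o dec.json --seed 1
armkin cluster dec*.json -o vocab.json --seed 1
armkin classify surfaces/ --vocab vocab.json -o report.json
armkin synth --vocab vocab.json --curvature-unit 0 --torsion-unit 1 -o behavior.tsv
```

Every run logs its resolved configuration and seeds; exit codes are 0
(success), 2 (validation error), 3 (numerical failure).

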