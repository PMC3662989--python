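"""Plain-text file formats for curves, surfaces, and analysis records.

- Curve-sequence files: delimited text with a header line and columns
  ``movement_id, frame_index, point_index, x, y, z`` (point_index ascending
  base to tip).  Output from synthesis round-trips through this format.
- Surface files: a delimited value matrix (rows: time grid, columns:
  arm-index grid) plus a JSON sidecar ``<path>.json`` holding the
  quantity, grid axes and provenance.
- Decomposition / vocabulary / classification records: JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import MovementEncoding, PrototypeSet
from .cluster import GapResult, UnitClustering
from .decompose import GaussianUnit, SurfaceDecomposition, unit_features
from .exceptions import ValidationError
from .geometry import BackboneCurve, KinematicSurface, MovementSequence
from .synth import BehaviorVocabulary

CURVE_COLUMNS = ["movement_id", "frame_index", "point_index", "x", "y", "z"]


# ---------------------------------------------------------------------------
# curve sequences
# ---------------------------------------------------------------------------


def read_curve_sequences(path) -> dict[str, MovementSequence]:
    """Read a curve-sequence file into movements keyed by movement_id.

    Frame times are the frame indices affinely normalized onto [0, 1].
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"curve file missing columns {missing}")
    out: dict[str, MovementSequence] = {}
    for mid, grp in df.groupby("movement_id", sort=True):
        frames = []
        idx = []
        for fi, fg in grp.groupby("frame_index", sort=True):
            fg = fg.sort_values("point_index")
            frames.append(BackboneCurve(fg[["x", "y", "z"]].to_numpy(float)))
            idx.append(float(fi))
        idx = np.asarray(idx)
        times = (idx - idx[0]) / (idx[-1] - idx[0]) if idx[-1] > idx[0] else idx
        out[str(mid)] = MovementSequence(curves=frames, times=times)
    return out


def write_curve_sequences(path, sequences: dict[str, MovementSequence], sep: str = "\t") -> None:
    rows = []
    for mid, seq in sequences.items():
        for fi, curve in enumerate(seq.curves):
            for pi, (x, y, z) in enumerate(curve.points):
                rows.append((mid, fi, pi, x, y, z))
    pd.DataFrame(rows, columns=CURVE_COLUMNS).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------


def write_surface(surface: KinematicSurface, path, provenance: dict | None = None) -> None:
    path = Path(path)
    np.savetxt(path, surface.values, delimiter="\t", fmt="%.12g")
    sidecar = {
        "quantity": surface.quantity,
        "s_axis": surface.s_axis.tolist(),
        "t_axis": surface.t_axis.tolist(),
        "provenance": provenance or {},
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_surface(path) -> KinematicSurface:
    path = Path(path)
    values = np.loadtxt(path, delimiter="\t", ndmin=2)
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise ValidationError(f"missing surface sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    return KinematicSurface(
        values, meta["quantity"], np.asarray(meta["s_axis"]), np.asarray(meta["t_axis"])
    )


# ---------------------------------------------------------------------------
# JSON records
# ---------------------------------------------------------------------------


def unit_to_dict(unit: GaussianUnit) -> dict:
    f = unit_features(unit)
    return {
        "w": unit.w,
        "mu": unit.mu.tolist(),
        "Sigma": unit.Sigma.tolist(),
        "features": {
            "center": list(f.center),
            "shape": f.shape,
            "size": f.size,
            "orientation_deg": f.orientation_deg,
            "weight": f.weight,
        },
    }


def unit_from_dict(d: dict) -> GaussianUnit:
    return GaussianUnit(float(d["w"]), np.asarray(d["mu"]), np.asarray(d["Sigma"]))


def write_decomposition(dec: SurfaceDecomposition, path, config: dict | None = None) -> None:
    rec = {
        "k": dec.k,
        "units": [unit_to_dict(u) for u in dec.units],
        "total_mass": dec.total_mass,
        "log_likelihood": dec.log_likelihood,
        "bic": dec.bic,
        "n_obs": dec.n_obs,
        "rmse": dec.rmse,
        "converged": dec.converged,
        "seed": dec.seed,
        "bic_by_k": dec.bic_by_k,
        "config": config or {},
    }
    Path(path).write_text(json.dumps(rec, indent=1, allow_nan=True))


def read_decomposition(path) -> SurfaceDecomposition:
    d = json.loads(Path(path).read_text())
    return SurfaceDecomposition(
        units=[unit_from_dict(u) for u in d["units"]],
        total_mass=d["total_mass"],
        log_likelihood=d["log_likelihood"],
        bic=d["bic"],
        n_obs=d["n_obs"],
        rmse=d["rmse"],
        converged=d.get("converged", True),
        seed=d.get("seed"),
        bic_by_k={int(k): v for k, v in d["bic_by_k"].items()} if d.get("bic_by_k") else None,
    )


def write_vocabulary(
    vocab: BehaviorVocabulary,
    path,
    clusterings: dict[str, UnitClustering] | None = None,
    gaps: dict[str, GapResult] | None = None,
) -> None:
    rec: dict = {
        "curvature_units": [unit_to_dict(u) for u in vocab.curvature_units],
        "torsion_units": [unit_to_dict(u) for u in vocab.torsion_units],
    }
    if clusterings:
        rec["cluster_sizes"] = {
            q: np.bincount(c.assignments, minlength=c.k).tolist()
            for q, c in clusterings.items()
        }
    if gaps:
        rec["gap"] = {
            q: {
                "k_range": g.k_range,
                "gap": g.gap.tolist(),
                "W_k": g.W_k.tolist(),
                "B": g.B,
                "k_star": g.k_star,
            }
            for q, g in gaps.items()
        }
    Path(path).write_text(json.dumps(rec, indent=1))


def read_vocabulary(path) -> BehaviorVocabulary:
    d = json.loads(Path(path).read_text())
    return BehaviorVocabulary(
        curvature_units=[unit_from_dict(u) for u in d["curvature_units"]],
        torsion_units=[unit_from_dict(u) for u in d["torsion_units"]],
    )


def write_classification(
    encodings: list[MovementEncoding], prototypes: PrototypeSet, path
) -> None:
    rec = {
        "movements": [
            {
                "movement_id": e.movement_id,
                "weights": e.weights.tolist(),
                "n_curvature": e.n_curvature,
                "residuals": e.residuals,
                "label": int(lab),
            }
            for e, lab in zip(encodings, prototypes.assignments)
        ],
        "prototype_weights": prototypes.prototype_weights.tolist(),
        "k": prototypes.k,
    }
    Path(path).write_text(json.dumps(rec, indent=1))
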