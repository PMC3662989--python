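"""Cubic smoothing-spline machinery shared by the geometry module.

The smoother minimizes the classical penalized objective
``p * sum |y_j - f(x_j)|^2 + (1 - p) * lam0 * int |f''|^2`` over natural
cubic splines, with the tradeoff expressed through a single parameter
``p`` in [0, 1] (p = 1: interpolation, p = 0: least-squares straight
line).  The roughness term carries de Boor's spacing normalization
``lam0 = h^3 / 6`` (h: mean site spacing) so that the useful range of p
does not depend on the sample count: p near 0.5 marks the transition and
the default p = 0.99 removes sample-to-sample jitter without attenuating
real bends.  For fixed data
sites the minimizer is linear in the data values, so we materialize the
smoother as an (n_eval x n_sites) matrix and cache it; backbone coordinate
smoothing and time-axis resampling then become plain matrix products.  The
linearity also makes rigid-motion invariance of downstream surfaces exact
up to floating-point rounding.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import make_interp_spline, make_smoothing_spline

from .exceptions import ValidationError

_CACHE: dict[tuple[bytes, bytes, float], np.ndarray] = {}
_CACHE_MAX = 128


def smoothing_operator(x: np.ndarray, x_eval: np.ndarray, p: float) -> np.ndarray:
    """Matrix S such that ``S @ y`` evaluates the smoothing spline of
    (x, y) at ``x_eval``, for any column(s) y.

    ``p = 0`` falls back to the least-squares line; fewer than 5 sites fall
    back to an interpolating spline of the highest supported degree (too few
    points to estimate roughness meaningfully).
    """
    x = np.asarray(x, dtype=float)
    x_eval = np.asarray(x_eval, dtype=float)
    if x.ndim != 1 or x_eval.ndim != 1:
        raise ValidationError("spline sites must be one-dimensional")
    if np.any(np.diff(x) <= 0):
        raise ValidationError("spline sites must be strictly increasing")
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"smoothing parameter p={p} outside [0, 1]")

    key = (x.tobytes(), x_eval.tobytes(), float(p))
    hit = _CACHE.get(key)
    if hit is not None:
        return hit

    n = x.size
    if p == 0.0:
        # zero weight on the residual term forces f'' == 0: straight line fit
        design = np.column_stack([np.ones(n), x])
        design_eval = np.column_stack([np.ones(x_eval.size), x_eval])
        mat = design_eval @ np.linalg.pinv(design)
    elif p == 1.0 or n < 5:
        k = min(3, n - 1)
        spl = make_interp_spline(x, np.eye(n), k=k)
        mat = spl(x_eval)
    else:
        # express p in spacing-normalized units (de Boor): the tradeoff
        # transition then sits near p ~ 0.5 regardless of site count, and
        # p = 0.99 is light jitter-removal rather than signal flattening
        h = (x[-1] - x[0]) / (n - 1)
        lam = (1.0 - p) / p * h**3 / 6.0
        spl = make_smoothing_spline(x, np.eye(n), lam=lam)
        mat = spl(x_eval)

    if len(_CACHE) >= _CACHE_MAX:
        _CACHE.pop(next(iter(_CACHE)))
    _CACHE[key] = mat
    return mat
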