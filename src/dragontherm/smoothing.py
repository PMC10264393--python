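"""Classical LOESS: local polynomial regression with tricube weights.

For each evaluation point the span-fraction nearest neighbours are weighted
by the tricube kernel and a degree-1 or degree-2 polynomial is fitted by
weighted least squares; the curve is materialised on a fixed grid and
predictions interpolate that grid.  Degree-d LOESS reproduces global
polynomials of degree ≤ d exactly, which the tests exploit as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LoessCurve", "fit_loess", "predict_loess"]


@dataclass(frozen=True)
class LoessCurve:
    span: float
    degree: int
    grid_x: np.ndarray
    grid_y: np.ndarray

    @property
    def valid_range(self) -> tuple[float, float]:
        return float(self.grid_x[0]), float(self.grid_x[-1])


def _loess_at(x0: float, x: np.ndarray, y: np.ndarray, q: int, degree: int) -> float:
    d = np.abs(x - x0)
    idx = np.argsort(d, kind="stable")[:q]
    xs, ys, ds = x[idx], y[idx], d[idx]
    dmax = ds.max()
    if dmax == 0:
        return float(ys.mean())
    w = (1.0 - np.minimum(ds / dmax, 1.0) ** 3) ** 3
    # centre at x0 so the intercept of the local fit is the prediction
    X = np.vander(xs - x0, N=degree + 1, increasing=True)
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], ys * sw, rcond=None)
    return float(beta[0])


def fit_loess(x, y, span: float = 0.75, degree: int = 2, grid_size: int = 200) -> LoessCurve:
    """Fit a LOESS curve and evaluate it on a regular grid over [min x, max x].

    Parameters
    ----------
    span : fraction of points in each local neighbourhood, in (0, 1].
    degree : local polynomial degree, 1 or 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    n = len(x)
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if not 0.0 < span <= 1.0:
        raise ValueError("span must lie in (0, 1]")
    if n < max(10, 3 * degree):
        raise ValueError(f"need at least {max(10, 3 * degree)} points")
    q = int(np.ceil(span * n))
    if q < degree + 2:
        raise ValueError("span too small for the requested degree")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    grid_x = np.linspace(xs[0], xs[-1], grid_size)
    grid_y = np.array([_loess_at(g, xs, ys, q, degree) for g in grid_x])
    return LoessCurve(span=span, degree=degree, grid_x=grid_x, grid_y=grid_y)


def predict_loess(curve: LoessCurve, x, with_flag: bool = False):
    """Interpolate the fitted grid; clamp (and optionally flag) outside it."""
    x_arr = np.asarray(x, dtype=float)
    lo, hi = curve.valid_range
    clamped = np.clip(x_arr, lo, hi)
    y = np.interp(clamped, curve.grid_x, curve.grid_y)
    out_of_range = (x_arr < lo) | (x_arr > hi)
    if np.ndim(x) == 0:
        y = float(y)
        out_of_range = bool(out_of_range)
    if with_flag:
        return y, out_of_range
    return y
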