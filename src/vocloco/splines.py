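"""Penalized cubic smoothing splines with the csaps ``p`` convention.

The fitted curve minimizes, over natural cubic splines ``f``,

    p * sum_j w_j (y_j - f(x_j))**2  +  (1 - p) * integral (f''(t))**2 dt

with unit weights by default.  ``p = 1`` interpolates the data, ``p = 0``
degenerates to the weighted least-squares line.  All smoothing parameters
quoted elsewhere in this package (0.10 for 1 Hz activity, 0.03/0.01 for
maturity trajectories, 0.1/0.3 for peri-event session/population curves,
1e-4 for developmental curves) are meaningful only under this convention.

The solver exploits the classical reduction to a pentadiagonal system in the
interior second derivatives (Reinsch / de Boor): with ``Q`` the second
divided-difference operator and ``R`` the tridiagonal Gram matrix of the
natural-spline second-derivative basis, the minimizer's knot values ``a``
satisfy

    (R + lam * Q^T W^{-1} Q) g = Q^T ybar,     a = ybar - lam * W^{-1} Q g

with ``lam = (1 - p) / p``; ``g`` are then exactly the interior second
derivatives of the fit, so the result is the natural cubic interpolant of
its own knot values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.linalg import solveh_banded


__all__ = ["SmoothingSpline", "fit_spline", "smooth_values"]


@dataclass
class SmoothingSpline:
    """A fitted penalized cubic smoothing spline.

    Attributes
    ----------
    knots : unique, increasing abscissa values the spline is anchored at.
    values : fitted spline values at the knots.
    p : smoothing parameter in [0, 1].
    """

    knots: np.ndarray
    values: np.ndarray
    p: float
    _pp: CubicSpline | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self._pp is None:
            if len(self.knots) >= 2:
                self._pp = CubicSpline(self.knots, self.values, bc_type="natural")
            else:
                # single knot: constant function
                c = float(self.values[0])
                self._pp = None
                self._const = c

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if self._pp is None:
            return np.full_like(x, self._const, dtype=float)
        return self._pp(x)

    @property
    def coefficients(self) -> np.ndarray:
        """Piecewise-polynomial coefficients (scipy PPoly layout)."""
        if self._pp is None:
            return np.array([[self._const]])
        return self._pp.c


def _collapse_duplicates(x, y, w):
    """Average replicated abscissae, accumulating weights.

    Minimizing the weighted residual sum over replicated points is identical
    (up to an additive constant) to minimizing over the unique points with
    count-summed weights and weighted-mean ordinates, so pooled data (e.g.
    many per-event traces sharing one relative-time grid) are handled exactly.
    """
    order = np.argsort(x, kind="stable")
    x, y, w = x[order], y[order], w[order]
    xu, inv = np.unique(x, return_inverse=True)
    wu = np.bincount(inv, weights=w)
    yu = np.bincount(inv, weights=w * y) / wu
    return xu, yu, wu


def _weighted_line(x, y, w):
    sw = w.sum()
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    slope = 0.0 if sxx == 0 else (w * (x - xm) * (y - ym)).sum() / sxx
    return ym + slope * (x - xm)


def smooth_values(xu, yu, wu, p):
    """Smoothing-spline knot values on an already unique, sorted abscissa.

    Low-overhead core shared by :func:`fit_spline` and the band internals in
    :mod:`vocloco.perievent` (which re-fit thousands of small splines whose
    knots coincide with the evaluation grid, so the knot values are the
    whole answer).
    """
    n = len(xu)
    if n < 4 or p == 0.0:
        return _weighted_line(xu, yu, wu) if n > 1 else yu.astype(float)
    if p == 1.0:
        return yu.astype(float)

    h = np.diff(xu)
    lam = (1.0 - p) / p
    m = n - 2

    dy = np.diff(yu) / h
    qty = dy[1:] - dy[:-1]

    r_diag = (h[:-1] + h[1:]) / 3.0
    r_off = h[1:-1] / 6.0

    iw = 1.0 / wu
    e0 = 1.0 / h[:-1]
    e2 = 1.0 / h[1:]
    e1 = -(e0 + e2)
    d0 = iw[:-2] * e0**2 + iw[1:-1] * e1**2 + iw[2:] * e2**2
    d1 = iw[1:-2] * e1[:-1] * e0[1:] + iw[2:-1] * e2[:-1] * e1[1:]
    d2 = iw[2:-2] * e2[:-2] * e0[2:]

    ab = np.zeros((3, m))
    ab[2, :] = r_diag + lam * d0
    if m > 1:
        ab[1, 1:] = r_off + lam * d1
    if m > 2:
        ab[0, 2:] = lam * d2

    g = solveh_banded(ab, qty)

    qg = np.zeros(n)
    qg[:-2] += e0 * g
    qg[1:-1] += e1 * g
    qg[2:] += e2 * g
    return yu - lam * iw * qg


def fit_spline(x, y, p, weights=None) -> SmoothingSpline:
    """Fit the penalized cubic smoothing spline at parameter ``p``.

    NaN pairs are dropped.  Requires at least 4 finite observations (pairs
    may share abscissae).  Replicated abscissae are collapsed by weighted
    averaging, which leaves the objective unchanged.

    Raises
    ------
    ValueError
        if fewer than 4 finite points remain or ``p`` is outside [0, 1].
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"smoothing parameter p={p} outside [0, 1]")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float).ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y, w = x[ok], y[ok], w[ok]
    if len(x) < 4:
        raise ValueError(f"need at least 4 finite points, got {len(x)}")

    xu, yu, wu = _collapse_duplicates(x, y, w)
    return SmoothingSpline(knots=xu, values=smooth_values(xu, yu, wu, p), p=p)
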