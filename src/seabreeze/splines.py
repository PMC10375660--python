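"""Cubic regression spline basis with an exact curvature penalty.

The basis is parameterized by the spline's values at k knots (a natural
cubic spline: second derivative zero at the boundary knots).  In this
parameterization the integrated squared second derivative is the exact
quadratic form  beta' D' B^{-1} D beta  with the classical tridiagonal B
and second-difference D matrices, so the penalty needs no quadrature.
Functions are extended linearly beyond the boundary knots (the natural
spline's own extrapolation); evaluation there is flagged by the caller.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve


def quantile_knots(x, k: int) -> np.ndarray:
    """k knots at the quantiles of the unique covariate values."""
    ux = np.unique(np.asarray(x, dtype=float))
    if ux.size < k:
        raise ValueError(
            f"need at least k={k} distinct covariate values (got {ux.size}); "
            "reduce the basis dimension k")
    return np.quantile(ux, np.linspace(0.0, 1.0, k))


class CubicRegressionSpline:
    """Natural cubic regression spline on fixed, strictly increasing knots."""

    def __init__(self, knots):
        knots = np.asarray(knots, dtype=float)
        if knots.ndim != 1 or knots.size < 4:
            raise ValueError("need at least 4 strictly increasing knots")
        if np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        self.knots = knots
        self.k = knots.size
        h = np.diff(knots)
        k = self.k
        B = np.zeros((k - 2, k - 2))
        D = np.zeros((k - 2, k))
        for i in range(k - 2):
            B[i, i] = (h[i] + h[i + 1]) / 3.0
            if i + 1 < k - 2:
                B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
            D[i, i] = 1.0 / h[i]
            D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
            D[i, i + 2] = 1.0 / h[i + 1]
        self._h = h
        # F maps knot values to second derivatives at ALL knots (natural BCs)
        self.F = np.zeros((k, k))
        self.F[1:-1] = solve(B, D, assume_a="pos")
        #: curvature penalty: beta' S beta = integral of f''(x)^2
        self.penalty = D.T @ self.F[1:-1]
        self.penalty = 0.5 * (self.penalty + self.penalty.T)

    def _segments(self, x):
        j = np.clip(np.searchsorted(self.knots, x, side="right") - 1, 0, self.k - 2)
        return j

    def basis(self, x) -> np.ndarray:
        """Design matrix rows mapping knot values to f(x)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        lo, hi = self.knots[0], self.knots[-1]
        inside = np.clip(x, lo, hi)
        X = self._basis_inside(inside)
        out_lo, out_hi = x < lo, x > hi
        if np.any(out_lo):
            X[out_lo] += (x[out_lo, None] - lo) * self._deriv_inside(np.full(out_lo.sum(), lo))
        if np.any(out_hi):
            X[out_hi] += (x[out_hi, None] - hi) * self._deriv_inside(np.full(out_hi.sum(), hi))
        return X

    def derivative_basis(self, x) -> np.ndarray:
        """Rows mapping knot values to f'(x) (exact, not finite-differenced)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return self._deriv_inside(np.clip(x, self.knots[0], self.knots[-1]))

    def _basis_inside(self, x):
        j = self._segments(x)
        h = self._h[j]
        xl, xr = self.knots[j], self.knots[j + 1]
        am = (xr - x) / h
        ap = (x - xl) / h
        cm = ((xr - x) ** 3 / h - h * (xr - x)) / 6.0
        cp = ((x - xl) ** 3 / h - h * (x - xl)) / 6.0
        X = cm[:, None] * self.F[j] + cp[:, None] * self.F[j + 1]
        rows = np.arange(x.size)
        X[rows, j] += am
        X[rows, j + 1] += ap
        return X

    def _deriv_inside(self, x):
        j = self._segments(x)
        h = self._h[j]
        xl, xr = self.knots[j], self.knots[j + 1]
        cm = (-3.0 * (xr - x) ** 2 / h + h) / 6.0
        cp = (3.0 * (x - xl) ** 2 / h - h) / 6.0
        X = cm[:, None] * self.F[j] + cp[:, None] * self.F[j + 1]
        rows = np.arange(x.size)
        X[rows, j] += -1.0 / h
        X[rows, j + 1] += 1.0 / h
        return X
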