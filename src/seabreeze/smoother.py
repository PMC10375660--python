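"""Penalized-spline additive model with AR(2) errors and a year intercept.

This is the engine behind every smooth fitted in the package:

    y_i = alpha + f(x_i) + b_{year(i)} + e_i,
    b_year ~ N(0, sigma2_year),   e ~ AR(2) within each ordinal date,

with f a cubic regression spline (k basis functions before the sum-to-zero
identifiability constraint), its curvature penalized by a smoothing
parameter lambda chosen by REML, and the year intercepts treated as a
ridge-penalized dummy block whose precision is likewise REML-estimated
(the usual random-effect-as-smooth equivalence).

Estimation alternates (a) penalized generalized least squares on data
whitened by the current AR(2) correlation within each date, with
(log lambda, log tau) maximizing the restricted likelihood via L-BFGS-B,
and (b) pooled Yule-Walker re-estimation of the AR coefficients from the
within-date residuals, until the parameters stabilise.  Profiling the AR
coefficients rather than folding them into the REML optimization is a
deliberate robustness choice (documented in the methods note).

The coefficient covariance stored on the fit is the Bayesian
(prior-inclusive) one, V = sigma2 (X'X + P)^{-1} on the whitened design —
the covariance simultaneous derivative intervals are defined on.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular, toeplitz

from .splines import CubicRegressionSpline, quantile_knots

_EIG_TOL = 1e-10


@dataclass(frozen=True)
class SplineSpec:
    """Cubic regression spline smooth: k columns before the constraint."""

    k: int = 12
    knots: np.ndarray | None = None

    def __post_init__(self):
        if self.k < 4:
            raise ValueError("basis dimension k must be >= 4")


@dataclass
class SplineFit:
    spec: SplineSpec
    knots: np.ndarray
    constraint: np.ndarray        # k x (k-1) null-space basis of the sum-to-zero constraint
    beta: np.ndarray              # intercept, smooth (k-1), year effects (q)
    covariance: np.ndarray        # Bayesian V_beta, same layout
    lambda_: float
    sigma2: float
    phi: tuple[float, ...]
    sigma2_year: float
    year_levels: list
    edf: float                    # total effective degrees of freedom
    edf_smooth: float
    x_range: tuple[float, float]
    converged: bool
    n_iter: int
    ar_order: int
    log: list = field(default_factory=list)

    # -- layout helpers -------------------------------------------------
    @property
    def n_smooth_cols(self) -> int:
        return self.constraint.shape[1]

    def _curve_rows(self, x) -> np.ndarray:
        """Design rows for alpha + f(x) (population level, year effect 0)."""
        crs = CubicRegressionSpline(self.knots)
        B = crs.basis(x) @ self.constraint
        rows = np.zeros((B.shape[0], self.beta.size))
        rows[:, 0] = 1.0
        rows[:, 1:1 + self.n_smooth_cols] = B
        return rows

    def _curve_derivative_rows(self, x) -> np.ndarray:
        """Exact-derivative design rows for f'(x)."""
        crs = CubicRegressionSpline(self.knots)
        B = crs.derivative_basis(x) @ self.constraint
        rows = np.zeros((B.shape[0], self.beta.size))
        rows[:, 1:1 + self.n_smooth_cols] = B
        return rows

    # -- serialization --------------------------------------------------
    def to_json(self) -> str:
        d = {
            "k": self.spec.k,
            "knots": self.knots.tolist(),
            "constraint": self.constraint.tolist(),
            "beta": self.beta.tolist(),
            "covariance": self.covariance.tolist(),
            "lambda": self.lambda_,
            "sigma2": self.sigma2,
            "phi": list(self.phi),
            "sigma2_year": self.sigma2_year,
            "year_levels": [str(y) for y in self.year_levels],
            "edf": self.edf,
            "edf_smooth": self.edf_smooth,
            "x_range": list(self.x_range),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "ar_order": self.ar_order,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SplineFit":
        d = json.loads(text)
        return cls(
            spec=SplineSpec(k=d["k"]),
            knots=np.asarray(d["knots"]),
            constraint=np.asarray(d["constraint"]),
            beta=np.asarray(d["beta"]),
            covariance=np.asarray(d["covariance"]),
            lambda_=d["lambda"],
            sigma2=d["sigma2"],
            phi=tuple(d["phi"]),
            sigma2_year=d["sigma2_year"],
            year_levels=d["year_levels"],
            edf=d["edf"],
            edf_smooth=d["edf_smooth"],
            x_range=tuple(d["x_range"]),
            converged=d["converged"],
            n_iter=d["n_iter"],
            ar_order=d["ar_order"],
        )


# ---------------------------------------------------------------------------
# basis construction
# ---------------------------------------------------------------------------

def build_basis(x, spec: SplineSpec):
    """Constrained design block, penalty and constraint basis for a smooth.

    Returns ``(X_smooth, S, Z, knots)`` where the sum-to-zero constraint
    sum_i f(x_i) = 0 has been absorbed: columns of ``X_smooth`` span the
    constrained function space, ``S = Z' S_full Z`` is the curvature
    penalty there, and ``Z`` maps constrained coefficients back to knot
    values for later evaluation.
    """
    x = np.asarray(x, dtype=float)
    knots = spec.knots if spec.knots is not None else quantile_knots(x, spec.k)
    crs = CubicRegressionSpline(knots)
    B = crs.basis(x)
    c = B.sum(axis=0)[:, None]                    # constraint vector
    Q, _ = np.linalg.qr(c, mode="complete")
    Z = Q[:, 1:]
    return B @ Z, Z.T @ crs.penalty @ Z, Z, np.asarray(knots)


# ---------------------------------------------------------------------------
# AR(2) machinery
# ---------------------------------------------------------------------------

def ar_acf(phi, nlags: int) -> np.ndarray:
    """Autocorrelation function of a stationary AR(p) process."""
    phi = np.asarray(phi, dtype=float)
    p = phi.size
    rho = np.zeros(nlags + 1)
    rho[0] = 1.0
    if p == 0:
        return rho
    if p == 1:
        for k in range(1, nlags + 1):
            rho[k] = phi[0] * rho[k - 1]
        return rho
    if p != 2:
        raise NotImplementedError("only AR orders 0..2 are supported")
    rho[1] = phi[0] / (1.0 - phi[1])
    for k in range(2, nlags + 1):
        rho[k] = phi[0] * rho[k - 1] + phi[1] * rho[k - 2]
    return rho


def is_stationary_ar2(phi) -> bool:
    p1, p2 = phi
    return (p2 + p1 < 1.0 - 1e-9) and (p2 - p1 < 1.0 - 1e-9) and (abs(p2) < 1.0 - 1e-9)


def project_stationary(phi, shrink: float = 0.95):
    """Shrink AR coefficients toward zero until inside the stationary region."""
    phi = np.asarray(phi, dtype=float)
    flagged = False
    while not is_stationary_ar2(phi if phi.size == 2 else np.r_[phi, 0.0][:2]):
        phi = phi * shrink
        flagged = True
    return tuple(phi), flagged


def pooled_yule_walker(residuals: np.ndarray, groups: np.ndarray, order: int = 2):
    """AR coefficients by Yule-Walker on residuals pooled across groups."""
    c = np.zeros(order + 1)
    n_tot = 0
    for g in pd.unique(groups):
        r = residuals[groups == g]
        n_tot += r.size
        for lag in range(order + 1):
            if r.size > lag:
                c[lag] += r[lag:] @ r[:r.size - lag] if lag else r @ r
    if n_tot == 0 or c[0] == 0:
        return tuple([0.0] * order)
    rho = c[1:] / c[0]
    if order == 1:
        phi = np.array([rho[0]])
    else:
        denom = 1.0 - rho[0] ** 2
        if denom <= 1e-12:
            return (0.0, 0.0)
        phi = np.array([rho[0] * (1.0 - rho[1]) / denom,
                        (rho[1] - rho[0] ** 2) / denom])
    phi_t, _ = project_stationary(phi)
    return phi_t


def _whiten_groups(arrays, groups, phi):
    """Left-multiply row blocks by L^{-1} with L L' = AR correlation matrix."""
    outs = [a.astype(float).copy() for a in arrays]
    cache: dict[int, np.ndarray] = {}
    for g in pd.unique(groups):
        m = groups == g
        n_g = int(m.sum())
        if n_g == 1:
            continue
        if n_g not in cache:
            R = toeplitz(ar_acf(phi, n_g - 1))
            cache[n_g] = cholesky(R, lower=True)
        L = cache[n_g]
        for a in outs:
            a[m] = solve_triangular(L, a[m], lower=True)
    return outs


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

def _logpdet(S: np.ndarray):
    ev = np.linalg.eigvalsh(S)
    pos = ev[ev > _EIG_TOL * ev.max()]
    return float(np.sum(np.log(pos))), int(pos.size)


def _reml_neg2(rho, Xw, yw, sqrt_S, n, sl_smooth, logpdet_S, rank_S,
               q_year, sl_year, m_null):
    """Profiled -2 restricted log-likelihood at log-smoothing parameters.

    Solved through the augmented least-squares QR (rows [X; sqrt(P)]) —
    unlike the normal equations this stays accurate for extreme lambda,
    where the unpenalized null-space component would otherwise be lost
    to conditioning.  Returns (value, beta, sigma2, R).
    """
    lam = np.exp(rho[0])
    p = Xw.shape[1]
    aug = [Xw]
    pen_smooth = np.zeros((sqrt_S.shape[0], p))
    pen_smooth[:, sl_smooth] = np.sqrt(lam) * sqrt_S
    aug.append(pen_smooth)
    logpdet_P = rank_S * rho[0] + logpdet_S
    if q_year:
        tau = np.exp(rho[1])
        pen_year = np.zeros((q_year, p))
        pen_year[:, sl_year] = np.sqrt(tau) * np.eye(q_year)
        aug.append(pen_year)
        logpdet_P += q_year * rho[1]
    M = np.vstack(aug)
    y_aug = np.concatenate([yw, np.zeros(M.shape[0] - n)])
    Q, R = np.linalg.qr(M)
    rdiag = np.abs(np.diag(R))
    if np.any(rdiag < 1e-12 * rdiag.max()):
        return np.inf, None, None, None
    beta = solve_triangular(R, Q.T @ y_aug)
    resid = y_aug - M @ beta
    # floor guards the exactly-representable case (RSS ~ 0): there the
    # profiled-sigma2 term goes flat and the determinant terms take over,
    # sending lambda to its bound (edf -> penalty null-space dimension)
    rss_pen = max(float(resid @ resid), 1e-24 * max(float(yw @ yw), 1.0))
    dof = n - m_null
    sigma2 = rss_pen / dof
    logdet_A = 2.0 * float(np.sum(np.log(rdiag)))
    neg2 = dof * np.log(sigma2) + logdet_A - logpdet_P
    return neg2, beta, sigma2, R


def fit(y, x, year=None, date=None, spec: SplineSpec | None = None,
        ar_order: int = 2, max_iter: int = 50, tol: float = 1e-6) -> SplineFit:
    """Fit the penalized-spline mixed model described in the module docstring.

    Parameters
    ----------
    y, x : arrays of the response and the smooth covariate (e.g. session
        mean airspeed vs hours before sunset).
    year : optional labels; with >= 2 levels a random intercept per year is
        estimated.
    date : optional ordinal-date labels; the AR(2) residual process runs
        within each date (independent across dates), in the order given.
        Required when ``ar_order > 0``.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise ValueError("y and x lengths differ")
    n = y.size
    spec = spec or SplineSpec()
    if ar_order > 0 and date is None:
        raise ValueError("date labels required for autocorrelated errors")
    if ar_order > 2:
        raise NotImplementedError("ar_order must be 0, 1 or 2")

    Xs, S, Z, knots = build_basis(x, spec)
    p_s = Xs.shape[1]
    cols = [np.ones((n, 1)), Xs]
    year_levels: list = []
    if year is not None:
        year = np.asarray(year)
        year_levels = list(pd.unique(year))
        if len(year_levels) >= 2:
            D = (year[:, None] == np.asarray(year_levels)[None, :]).astype(float)
            cols.append(D)
        else:
            year_levels = []
    X = np.hstack(cols)
    p = X.shape[1]
    q_year = len(year_levels)
    sl_smooth = slice(1, 1 + p_s)
    sl_year = slice(1 + p_s, 1 + p_s + q_year)
    logpdet_S, rank_S = _logpdet(S)
    ev, U = np.linalg.eigh(S)
    keep = ev > _EIG_TOL * ev.max()
    sqrt_S = (np.sqrt(ev[keep])[:, None] * U[:, keep].T)   # rows: sqrt_S' sqrt_S = S
    m_null = p - rank_S - q_year          # unpenalized dimensions

    if date is not None:
        date = np.asarray(date)
        if year is not None:
            groups = pd.Series(list(zip(np.asarray(year), date))).astype(str).to_numpy()
        else:
            groups = date
    else:
        groups = None

    phi = tuple([0.0] * ar_order)
    rho = np.zeros(2 if q_year else 1)
    log: list = []
    converged = False
    it = 0
    beta = None
    for it in range(1, max_iter + 1):
        if ar_order and any(phi):
            Xw, yw = _whiten_groups([X, y[:, None]], groups, phi)
            yw = yw[:, 0]
        else:
            Xw, yw = X, y
        res = optimize.minimize(
            lambda r: _reml_neg2(r, Xw, yw, sqrt_S, n, sl_smooth,
                                 logpdet_S, rank_S, q_year, sl_year, m_null)[0],
            rho, method="L-BFGS-B",
            bounds=[(-15.0, 20.0)] * rho.size,
            # objective magnitude ~ n log sigma2: the default 1e-8 FD step
            # drowns in float noise, stalling the very flat degenerate cases
            options={"eps": 1e-5, "maxfun": 500})
        rho_new = res.x
        _, beta, sigma2, _ = _reml_neg2(rho_new, Xw, yw, sqrt_S, n, sl_smooth,
                                        logpdet_S, rank_S, q_year, sl_year, m_null)
        if ar_order:
            resid = y - X @ beta
            phi_new = pooled_yule_walker(resid, groups, ar_order)
        else:
            phi_new = phi
        delta = max(
            float(np.max(np.abs(rho_new - rho))) if rho.size else 0.0,
            max((abs(a - b) for a, b in zip(phi_new, phi)), default=0.0),
        )
        log.append({"iter": it, "lambda": float(np.exp(rho_new[0])),
                    "phi": list(phi_new), "delta": delta})
        rho, phi = rho_new, phi_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("smoother did not converge; returning last iterate")

    # final quantities at the converged parameters
    if ar_order and any(phi):
        Xw, yw = _whiten_groups([X, y[:, None]], groups, phi)
        yw = yw[:, 0]
    else:
        Xw, yw = X, y
    neg2, beta, sigma2, R = _reml_neg2(rho, Xw, yw, sqrt_S, n, sl_smooth,
                                       logpdet_S, rank_S, q_year, sl_year, m_null)
    lam = float(np.exp(rho[0]))
    tau = float(np.exp(rho[1])) if q_year else np.inf
    XtX = Xw.T @ Xw
    R_inv = solve_triangular(R, np.eye(p))
    A_inv = R_inv @ R_inv.T
    Vb = sigma2 * A_inv
    Vb = 0.5 * (Vb + Vb.T)
    influence = A_inv @ XtX
    edf = float(np.trace(influence))
    edf_smooth = float(np.trace(influence[sl_smooth, sl_smooth]))
    sigma2_year = sigma2 / tau if q_year else 0.0

    return SplineFit(
        spec=spec, knots=knots, constraint=Z, beta=beta, covariance=Vb,
        lambda_=lam, sigma2=float(sigma2), phi=tuple(float(v) for v in phi),
        sigma2_year=float(sigma2_year), year_levels=year_levels,
        edf=edf, edf_smooth=edf_smooth,
        x_range=(float(x.min()), float(x.max())),
        converged=converged, n_iter=it, ar_order=ar_order, log=log)


def predict(fit: SplineFit, x_new, se: bool = True):
    """Population-level fitted curve alpha + f(x) with pointwise SEs.

    Points outside the training range are evaluated on the natural
    spline's linear extension and flagged via the returned mask.
    """
    x_new = np.atleast_1d(np.asarray(x_new, dtype=float))
    rows = fit._curve_rows(x_new)
    fitted = rows @ fit.beta
    outside = (x_new < fit.x_range[0]) | (x_new > fit.x_range[1])
    if not se:
        return fitted, outside
    se_vals = np.sqrt(np.maximum(0.0, np.einsum("ij,jk,ik->i", rows,
                                                fit.covariance, rows)))
    return fitted, se_vals, outside
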