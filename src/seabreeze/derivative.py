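"""First derivative of a fitted smooth with simultaneous confidence bands.

The rate of change f'(x) of a fitted smooth is estimated by forward finite
differences of the predicted curve, (f(x+eps) - f(x))/eps with eps = 1e-7
by default, on a grid of N = 1000 points spanning the observed covariate
range.  Because prediction is linear in the coefficients, the derivative
is itself a linear functional  d(x) = X_d(x) beta, so its pointwise
standard error follows from the Bayesian coefficient covariance, and a
95% *simultaneous* band is obtained by posterior simulation: draw n_sim
coefficient vectors from N(beta_hat, V_beta), form each draw's derivative
curve, and take the level-quantile m* of the maximum over the grid of the
|deviation|/SE statistic.  Periods where the simultaneous band excludes
zero are labelled significant increases (lower bound > 0) or decreases
(upper bound < 0) — the package's change-detection primitive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .smoother import SplineFit


@dataclass(frozen=True)
class Segment:
    x_start: float
    x_end: float
    sign: str                       # "increase" | "decrease"


@dataclass
class DerivativeResult:
    x: np.ndarray
    derivative: np.ndarray
    se: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    crit: float                     # simultaneous critical multiplier m*
    level: float
    n_sim: int
    eps: float
    seed: int | None
    segments: list[Segment] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        sig = np.zeros(self.x.size, dtype=int)
        sig[self.lower > 0] = 1
        sig[self.upper < 0] = -1
        return pd.DataFrame({
            "x": self.x, "derivative": self.derivative, "se": self.se,
            "lower": self.lower, "upper": self.upper,
            "significant": sig != 0,
            "sign": np.where(sig > 0, "increase", np.where(sig < 0, "decrease", "")),
        })

    def segments_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.segments],
                            columns=["x_start", "x_end", "sign"])


def _difference_rows(fit: SplineFit, x: np.ndarray, eps: float, scheme: str):
    """Design rows of the finite-difference derivative functional."""
    lo, hi = fit.x_range
    if scheme == "forward":
        # step inward at the upper endpoint so we never leave the range
        x0 = np.where(x + eps > hi, x - eps, x)
        x1 = x0 + eps
    elif scheme == "central":
        x0 = np.clip(x - eps / 2, lo, hi - eps)
        x1 = x0 + eps
    elif scheme == "exact":
        return fit._curve_derivative_rows(x)
    else:
        raise ValueError(f"unknown difference scheme {scheme!r}")
    return (fit._curve_rows(x1) - fit._curve_rows(x0)) / eps


def first_derivative(fit: SplineFit, n_points: int = 1000, eps: float = 1e-7,
                     scheme: str = "forward"):
    """f'(x) on an n_points grid spanning the training covariate range."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    if eps < 1e-9:
        warnings.warn("eps below 1e-9 risks floating-point cancellation")
    x = np.linspace(fit.x_range[0], fit.x_range[1], n_points)
    Xd = _difference_rows(fit, x, eps, scheme)
    return x, Xd @ fit.beta


def simultaneous_band(fit: SplineFit, n_points: int = 1000, n_sim: int = 10_000,
                      level: float = 0.95, eps: float = 1e-7,
                      scheme: str = "forward", seed: int | None = None,
                      rng: np.random.Generator | None = None) -> DerivativeResult:
    """Derivative curve with a level-simultaneous confidence band.

    The band is  f'(x) +- m* SE(x)  with m* the level-quantile of the
    max-over-grid standardized absolute deviation across n_sim draws from
    the coefficient posterior N(beta_hat, V_beta).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    x = np.linspace(fit.x_range[0], fit.x_range[1], n_points)
    Xd = _difference_rows(fit, x, eps, scheme)
    deriv = Xd @ fit.beta
    V = fit.covariance
    se = np.sqrt(np.maximum(0.0, np.einsum("ij,jk,ik->i", Xd, V, Xd)))
    if np.all(se == 0):                       # degenerate zero-covariance limit
        res = DerivativeResult(x, deriv, se, deriv.copy(), deriv.copy(),
                               0.0, level, n_sim, eps, seed)
        res.segments = significant_segments(res)
        return res

    try:
        L = np.linalg.cholesky(V + 1e-12 * np.trace(V) / V.shape[0] * np.eye(V.shape[0]))
    except np.linalg.LinAlgError:
        warnings.warn("singular coefficient covariance; using eigenvalue pseudo-root")
        w, U = np.linalg.eigh(V)
        L = U * np.sqrt(np.clip(w, 0.0, None))
    G = (Xd @ L)                               # (N, p): maps std-normal draws to curves
    safe_se = np.where(se > 0, se, np.inf)
    max_stat = np.empty(n_sim)
    chunk = max(1, int(2e6) // x.size)
    for i0 in range(0, n_sim, chunk):
        m = min(chunk, n_sim - i0)
        Zd = rng.standard_normal((m, G.shape[1]))
        dev = Zd @ G.T                         # (m, N) deviation curves
        max_stat[i0:i0 + m] = np.max(np.abs(dev) / safe_se[None, :], axis=1)
    crit = float(np.quantile(max_stat, level))
    res = DerivativeResult(x, deriv, se, deriv - crit * se, deriv + crit * se,
                           crit, level, n_sim, eps, seed)
    res.segments = significant_segments(res)
    return res


def significant_segments(result: DerivativeResult) -> list[Segment]:
    """Maximal runs of grid points whose simultaneous band excludes zero."""
    segs: list[Segment] = []
    sig = np.zeros(result.x.size, dtype=int)
    sig[result.lower > 0] = 1
    sig[result.upper < 0] = -1
    i = 0
    n = sig.size
    while i < n:
        if sig[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and sig[j + 1] == sig[i]:
            j += 1
        segs.append(Segment(float(result.x[i]), float(result.x[j]),
                            "increase" if sig[i] > 0 else "decrease"))
        i = j + 1
    return segs
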