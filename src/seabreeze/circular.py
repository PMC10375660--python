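"""Circular descriptive statistics and simplified diurnal wind-trend models.

The Rayleigh test uses the standard large-sample approximation with the
second-order small-n correction (Zar 1999, eq. 27.4); the exact variant
used by R's `circular` package differs negligibly at the sample sizes in
play here and the choice is documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CircularSummary:
    mean_direction: float     # degrees in [0, 360)
    r: float                  # resultant length in [0, 1]
    circular_sd: float        # degrees, sqrt(-2 ln r)
    rayleigh_p: float
    n: int


def circular_summary(angles_deg) -> CircularSummary:
    """Mean direction, resultant length, circular SD and Rayleigh p-value."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    a = a[~np.isnan(a)]
    n = a.size
    if n == 0:
        raise ValueError("no angles supplied")
    z = np.exp(1j * a).mean()
    r = float(np.abs(z))
    mean = float(np.degrees(np.angle(z)) % 360.0) % 360.0  # fp: never report 360.0
    csd = float(np.degrees(np.sqrt(max(0.0, -2.0 * np.log(r))))) if r > 0 else np.inf
    Z = n * r * r
    p = np.exp(-Z) * (1.0 + (2.0 * Z - Z * Z) / (4.0 * n)
                      - (24.0 * Z - 132.0 * Z**2 + 76.0 * Z**3 - 9.0 * Z**4) / (288.0 * n * n))
    p = float(np.clip(p, np.finfo(float).tiny, 1.0))
    return CircularSummary(mean, r, csd, p, n)


def circular_mean(angles_deg) -> float:
    a = np.radians(np.asarray(angles_deg, dtype=float))
    a = a[~np.isnan(a)]
    if a.size == 0:
        return np.nan
    return float(np.degrees(np.angle(np.exp(1j * a).mean())) % 360.0) % 360.0


def unwrap_directions(dir_deg) -> np.ndarray:
    """Directions (deg) unwrapped to a continuous radian series within a day.

    The sea-breeze stays within a half-circle over a day, so feeding
    unwrapped radians to a linear model is a documented simplification in
    place of full circular regression.
    """
    return np.unwrap(np.radians(np.asarray(dir_deg, dtype=float)))


def rose_table(angles_deg, bin_width: float = 10.0) -> pd.DataFrame:
    """Direction-frequency table for rose diagrams."""
    edges = np.arange(0.0, 360.0 + bin_width, bin_width)
    counts, _ = np.histogram(np.asarray(angles_deg, dtype=float) % 360.0, bins=edges)
    return pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:],
                         "count": counts,
                         "frequency": counts / max(1, counts.sum())})


@dataclass
class WindTrendFit:
    """Per-year quadratic trends of a wind variable vs hours before sunset.

    Date-level random intercepts are absorbed by within-date centering
    (two-stage estimation): slopes come from the within-date estimator, the
    intercept from the year's grand means, and the between-date variance of
    the date means estimates the random-intercept variance.
    """

    response: str
    coefficients: pd.DataFrame          # year, b0, b1, b2, se_b1, se_b2, sigma_date, n
    homogeneity: dict = field(default_factory=dict)

    def predict(self, year, hours) -> np.ndarray:
        row = self.coefficients.set_index("year").loc[year]
        h = np.asarray(hours, dtype=float)
        return row["b0"] + row["b1"] * h + row["b2"] * h * h


def wind_trend_model(sessions: pd.DataFrame, response: str = "wind_speed",
                     time_col: str = "hours_before_sunset") -> WindTrendFit:
    """Quadratic-in-time trend per year with date-level random intercept.

    ``response`` may be "wind_speed" or "wind_dir_rad" (pre-unwrapped
    radians).  Raises on rank deficiency (fewer than 3 distinct times),
    naming the offending year.
    """
    rows = []
    pooled_rss, pooled_n = 0.0, 0
    within = {}
    for year, g in sessions.groupby("year"):
        t = g[time_col].to_numpy(dtype=float)
        y = g[response].to_numpy(dtype=float)
        if np.unique(t).size < 3:
            raise ValueError(f"year {year}: need >= 3 distinct time points for a quadratic")
        X = np.column_stack([t, t * t])
        date = g["ordinal_date"].to_numpy()
        # within-date demeaning absorbs the date intercepts
        yc, Xc = y.copy(), X.copy()
        date_means = {}
        for d in np.unique(date):
            m = date == d
            date_means[d] = (y[m].mean(), X[m].mean(axis=0))
            yc[m] -= y[m].mean()
            Xc[m] -= X[m].mean(axis=0)
        if np.linalg.matrix_rank(Xc) < 2:
            raise ValueError(f"year {year}: within-date design is rank deficient")
        beta, rss_arr, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        resid = yc - Xc @ beta
        rss = float(resid @ resid)
        n, n_dates = len(y), len(date_means)
        dof = max(1, n - n_dates - 2)
        sigma2 = rss / dof
        XtX_inv = np.linalg.inv(Xc.T @ Xc)
        se = np.sqrt(np.diag(XtX_inv) * sigma2)
        b0 = y.mean() - beta[0] * X[:, 0].mean() - beta[1] * X[:, 1].mean()
        # date-intercept variance from between-date spread of adjusted means
        dres = [ym - b0 - Xm @ beta for ym, Xm in date_means.values()]
        sigma_date = float(np.std(dres, ddof=1)) if n_dates > 1 else 0.0
        rows.append(dict(year=year, b0=b0, b1=beta[0], b2=beta[1],
                         se_b1=se[0], se_b2=se[1], sigma_date=sigma_date, n=n))
        within[year] = (Xc, yc, rss)
        pooled_rss += rss
        pooled_n += n
    coef = pd.DataFrame(rows)

    # homogeneity: pooled within-date fit vs per-year fits (extra-sum-of-squares F)
    homog = {}
    if len(within) > 1:
        Xall = np.vstack([v[0] for v in within.values()])
        yall = np.concatenate([v[1] for v in within.values()])
        beta_p, *_ = np.linalg.lstsq(Xall, yall, rcond=None)
        rss_pooled = float(np.sum((yall - Xall @ beta_p) ** 2))
        rss_full = sum(v[2] for v in within.values())
        k = len(within)
        df1 = 2 * (k - 1)
        df2 = pooled_n - 2 * k - sum(sessions.groupby("year")["ordinal_date"].nunique())
        if df2 > 0 and rss_full > 0:
            from scipy import stats
            # clamp: fp noise can make the nested RSS marginally smaller
            F = (max(rss_pooled - rss_full, 0.0) / df1) / (rss_full / df2)
            homog = {"F": float(F), "df1": df1, "df2": int(df2),
                     "p": float(stats.f.sf(F, df1, df2))}
    return WindTrendFit(response=response, coefficients=coef, homogeneity=homog)
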