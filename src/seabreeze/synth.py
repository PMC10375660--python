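"""Synthetic sea-breeze days and bird sessions with known ground truth.

The generator encodes the stated world of the analysis: a surface wind
that rotates clockwise through the day from blowing towards ~E (87.1 deg,
10 h before sunset) to ~SE (131.1 deg, 3 h before sunset) while its speed
increases quadratically; birds holding a near-constant southward goal
direction (187.7 deg) whose airspeed responds linearly to tailwind; and a
session structure of 15-min means nested in days nested in years, with
AR(2) serial correlation of the session-level noise within each day
(independent across days).

Ground-truth per-session expectations are emitted as explicit ``true_*``
columns so recovery tests never re-derive them from generator internals.
One global seed expands to per-day substreams (numpy SeedSequence.spawn),
so any single day is reproducible on its own.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kinematics, solar
from .kinematics import AIRSPEED_CAP


class ConfigurationError(ValueError):
    """Invalid scenario or pipeline configuration."""


#: simulation window in hours before sunset (the study's analysis window)
DAY_WINDOW = (-10.0, -3.0)


@dataclass(frozen=True)
class WindScenario:
    """Diurnal sea-breeze wind: clockwise rotation + quadratic speed-up.

    ``speed_coefs = (c0, c1, c2)`` give speed = c0 + c1 h + c2 h^2 in m/s
    with h the (negative) hours before sunset.  Defaults rotate from the
    observed morning mean (87.1 deg) to the afternoon mean (131.1 deg) and
    run the quadratic through ~1.5 m/s at -10 h, the observed 4.1 m/s mean
    mid-window and ~5.2 m/s at -3 h.
    """

    dir_start: float = 87.1
    dir_end: float = 131.1
    speed_coefs: tuple[float, float, float] = (4.949, -0.2673, -0.06122)
    dir_noise_sd: float = 25.0
    speed_noise_sd: float = 0.8
    sampling_interval: float = 10.0          # minutes

    def mean_direction(self, hours) -> np.ndarray:
        """Shortest-arc circular interpolation over the day window.

        A 180-degree tie is broken clockwise, matching the sea-breeze's
        clockwise rotation.
        """
        h = np.asarray(hours, dtype=float)
        delta = (self.dir_end - self.dir_start) % 360.0
        if delta > 180.0:
            delta -= 360.0
        # delta == 180 stays +180: clockwise tie-break
        frac = (h - DAY_WINDOW[0]) / (DAY_WINDOW[1] - DAY_WINDOW[0])
        return (self.dir_start + delta * frac) % 360.0

    def mean_speed(self, hours) -> np.ndarray:
        h = np.asarray(hours, dtype=float)
        c0, c1, c2 = self.speed_coefs
        return c0 + c1 * h + c2 * h * h


@dataclass(frozen=True)
class BirdScenario:
    """Population of soaring migrants with a linear airspeed-tailwind rule."""

    goal_direction: float = 187.7
    airspeed_base: float = 16.5
    airspeed_tailwind_slope: float = -0.6     # m/s per m/s of tailwind, <= 0
    compensation_mode: str = "full"           # full | partial | drift
    compensation_kappa: float = 1.0           # partial mode: 0 = drift, 1 = full
    track_dir_concentration: float | None = 200.0   # von Mises kappa; None = exact
    session_noise_sd: float = 0.4             # marginal SD of the AR(2) noise, m/s
    ar_coefs: tuple[float, float] = (0.5, 0.2)
    n_years: int = 7
    days_per_year: int = 20
    sessions_per_day: int = 28
    tracks_per_session: int = 20
    seed: int | None = None

    def __post_init__(self):
        p1, p2 = self.ar_coefs
        if not (p2 + p1 < 1 and p2 - p1 < 1 and abs(p2) < 1):
            raise ConfigurationError("AR(2) coefficients are not stationary")
        for name in ("n_years", "days_per_year", "sessions_per_day", "tracks_per_session"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.compensation_mode not in ("full", "partial", "drift"):
            raise ConfigurationError("compensation_mode must be full, partial or drift")
        if not 0.0 <= self.compensation_kappa <= 1.0:
            raise ConfigurationError("compensation_kappa must lie in [0, 1]")


def ar2_noise(rng: np.random.Generator, n: int, phi: tuple[float, float],
              marginal_sd: float, burn: int = 100) -> np.ndarray:
    """Stationary AR(2) series with the requested MARGINAL standard deviation."""
    if marginal_sd == 0.0 or n == 0:
        return np.zeros(n)
    p1, p2 = phi
    gamma_ratio = (1.0 + p2) * ((1.0 - p2) ** 2 - p1 ** 2) / (1.0 - p2)
    innov_sd = marginal_sd * np.sqrt(gamma_ratio)
    e = rng.standard_normal(n + burn) * innov_sd
    out = np.zeros(n + burn)
    for t in range(n + burn):
        out[t] = e[t]
        if t >= 1:
            out[t] += p1 * out[t - 1]
        if t >= 2:
            out[t] += p2 * out[t - 2]
    return out[burn:]


def simulate_wind_day(scenario: WindScenario, date: dt.date,
                      seed: int | None = None,
                      rng: np.random.Generator | None = None,
                      location: tuple[float, float] = solar.LATRUN) -> pd.DataFrame:
    """One day of 10-min wind records over the -10..-3 h pre-sunset window."""
    span_min = (DAY_WINDOW[1] - DAY_WINDOW[0]) * 60.0
    if scenario.sampling_interval <= 0 or span_min % scenario.sampling_interval > 1e-9:
        raise ConfigurationError("sampling_interval must divide the day window")
    if rng is None:
        if seed is None:
            seed = int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
            warnings.warn(f"no seed supplied; drew seed={seed}")
        rng = np.random.default_rng(seed)
    hours = DAY_WINDOW[0] + np.arange(int(span_min / scenario.sampling_interval) + 1) \
        * scenario.sampling_interval / 60.0
    _, sunset = solar.sun_events_utc(date, *location)
    direction = scenario.mean_direction(hours)
    if scenario.dir_noise_sd > 0:
        direction = direction + rng.normal(0.0, scenario.dir_noise_sd, hours.size)
    speed = scenario.mean_speed(hours)
    if scenario.speed_noise_sd > 0:
        speed = speed + rng.normal(0.0, scenario.speed_noise_sd, hours.size)
    return pd.DataFrame({
        "timestamp": sunset + pd.to_timedelta(hours, unit="h"),
        "hours_before_sunset": hours,
        "wind_speed": np.clip(speed, 0.0, None),
        "wind_dir": direction % 360.0,
        "convention": "towards",
    })


def _session_truth(wind_speed, wind_dir, birds: BirdScenario):
    """Noise-free wind-triangle solution for one session's conditions."""
    goal = birds.goal_direction
    w_t, w_c = kinematics.wind_components(wind_speed, wind_dir, goal)
    v_a = birds.airspeed_base + birds.airspeed_tailwind_slope * w_t
    truncated = False
    if v_a > AIRSPEED_CAP:
        warnings.warn("required airspeed exceeds the physical cap; truncating")
        v_a, truncated = AIRSPEED_CAP, True
    if v_a < 0:
        v_a, truncated = 0.0, True
    kappa = {"full": 1.0, "drift": 0.0, "partial": birds.compensation_kappa}[
        birds.compensation_mode]
    # cross component of the wind w.r.t. the goal axis (signed, E/N frame)
    w_perp = wind_speed * np.sin(np.radians(wind_dir - goal))
    arg = np.clip(w_perp / v_a if v_a > 0 else 0.0, -1.0, 1.0)
    if abs(w_perp) > v_a:
        truncated = True
    heading = goal - kappa * np.degrees(np.arcsin(arg))
    ae = v_a * np.sin(np.radians(heading)) + wind_speed * np.sin(np.radians(wind_dir))
    an = v_a * np.cos(np.radians(heading)) + wind_speed * np.cos(np.radians(wind_dir))
    v_g = float(np.hypot(ae, an))
    theta_b = float(np.degrees(np.arctan2(ae, an)) % 360.0)
    v_s = float(kinematics.lateral_component_of_airspeed(v_a, theta_b, goal))
    return dict(w_t=float(w_t), w_c=float(w_c), v_a=float(v_a), heading=float(heading),
                v_g=v_g, theta_b=theta_b, v_s=v_s, truncated=truncated)


def simulate_sessions(wind: pd.DataFrame, birds: BirdScenario,
                      seed: int | None = None,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sessions for one day, driven by that day's wind records.

    Each session takes the nearest-in-time wind record, solves the wind
    triangle for the scenario's compensation mode, adds one AR(2) noise
    stream to airspeed (the heading rule is then re-applied, so every
    emitted session still satisfies air + wind = ground exactly), and
    averages ``tracks_per_session`` von-Mises-scattered track directions.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    h_lo, h_hi = DAY_WINDOW
    h_sess = h_lo + (h_hi - h_lo) / birds.sessions_per_day * np.arange(birds.sessions_per_day)
    wh = wind["hours_before_sunset"].to_numpy()
    if wh.min() > h_sess.min() or wh.max() < h_sess.max() - 0.25:
        raise ConfigurationError("wind records do not cover the session window")
    noise = ar2_noise(rng, birds.sessions_per_day, birds.ar_coefs, birds.session_noise_sd)
    sunset = wind["timestamp"].iloc[0] - pd.to_timedelta(wh[0], unit="h")
    rows = []
    for i, h in enumerate(h_sess):
        j = int(np.argmin(np.abs(wh - h)))
        w_spd = float(wind["wind_speed"].iloc[j])
        w_dir = float(wind["wind_dir"].iloc[j])
        truth = _session_truth(w_spd, w_dir, birds)
        # noisy session: perturb airspeed, re-solve the triangle with the same rule
        noisy = dict(truth)
        if noise[i] != 0.0:
            b2 = BirdScenario(**{**birds.__dict__,
                                 "airspeed_base": birds.airspeed_base + noise[i],
                                 "seed": None})
            noisy = _session_truth(w_spd, w_dir, b2)
        theta_b = noisy["theta_b"]
        n_tracks = birds.tracks_per_session
        if birds.track_dir_concentration is not None and np.isfinite(
                birds.track_dir_concentration):
            dirs = np.degrees(rng.vonmises(np.radians(theta_b),
                                           birds.track_dir_concentration, n_tracks))
            from .circular import circular_mean
            theta_b_obs = circular_mean(dirs)
        else:
            theta_b_obs = theta_b
        ts = sunset + pd.to_timedelta(h, unit="h")
        rows.append({
            "session_time": ts, "hours_before_sunset": float(h),
            "n_tracks": n_tracks,
            "v_g": noisy["v_g"], "v_a": noisy["v_a"], "v_s": noisy["v_s"],
            "w_t": noisy["w_t"], "w_c": noisy["w_c"],
            "theta_b": theta_b_obs, "heading": noisy["heading"],
            "wind_speed": w_spd, "wind_dir": w_dir,
            "true_v_a": truth["v_a"], "true_v_g": truth["v_g"],
            "true_v_s": truth["v_s"], "true_theta_b": truth["theta_b"],
            "true_w_t": truth["w_t"], "true_w_c": truth["w_c"],
            "truncated": bool(noisy["truncated"] or truth["truncated"]),
        })
    return pd.DataFrame(rows)


def flat_then_decline_scenario() -> tuple[WindScenario, BirdScenario]:
    """Scenario whose true airspeed is flat early, then declines.

    The wind starts perpendicular to the goal direction (no tailwind) with
    near-zero speed and rotates/strengthens so the tailwind only becomes
    appreciable from about 7 h before sunset; with the linear
    airspeed-tailwind rule the expected airspeed is flat (|rate| < 0.06
    m/s per hour) before -8 h and declines at 0.35-0.57 m/s per hour over
    the last two hours — the regime the change-detection method is meant
    to pick out.
    """
    wind = WindScenario(dir_start=97.7, dir_end=131.1,
                        speed_coefs=(10.0, 2.0, 0.1),
                        dir_noise_sd=12.0, speed_noise_sd=0.4)
    birds = BirdScenario(n_years=2, days_per_year=10)
    return wind, birds


def season_dates(year: int, n_days: int) -> list[dt.date]:
    """n_days dates evenly spread over the Aug 16 - Sep 30 migration season."""
    start = dt.date(year, 8, 16)
    season_len = (dt.date(year, 9, 30) - start).days
    offsets = np.unique(np.round(np.linspace(0, season_len, n_days)).astype(int))
    return [start + dt.timedelta(days=int(o)) for o in offsets]


def simulate_study(wind_scenario: WindScenario | None = None,
                   bird_scenario: BirdScenario | None = None,
                   seed: int | None = None,
                   first_year: int = 2005) -> pd.DataFrame:
    """Multi-year session table with ground truth, per-day substreams."""
    wind_scenario = wind_scenario or WindScenario()
    birds = bird_scenario or BirdScenario()
    if seed is None:
        seed = birds.seed
    root = np.random.SeedSequence(seed)
    frames = []
    for yi in range(birds.n_years):
        year = first_year + yi
        for date in season_dates(year, birds.days_per_year):
            child = np.random.SeedSequence(
                entropy=root.entropy if root.entropy is not None else 0,
                spawn_key=(yi, date.toordinal()))
            rng = np.random.default_rng(child)
            wind = simulate_wind_day(wind_scenario, date, rng=rng)
            sess = simulate_sessions(wind, birds, rng=rng)
            sess.insert(0, "year", year)
            sess.insert(1, "ordinal_date", date.timetuple().tm_yday)
            frames.append(sess)
    return pd.concat(frames, ignore_index=True)


def simulate_tracks(sessions: pd.DataFrame, wind_scenario: WindScenario | None = None,
                    seed: int | None = None,
                    location: tuple[float, float] = solar.LATRUN,
                    duration_s: float = 90.0) -> pd.DataFrame:
    """Raw radar-style track records consistent with a session table.

    Each session row is expanded to ``n_tracks`` short tracks: random start
    points within ~25 km of the radar, endpoints displaced by the session's
    ground vector over ``duration_s``, altitudes around 800 m adjusted for
    a mild climb.  Intended to feed the reading/annotation/aggregation path
    end-to-end.
    """
    from . import geo

    rng = np.random.default_rng(seed)
    lon0, lat0 = location
    m_lat, m_lon = geo.degree_lengths(lat0)
    rows = []
    tid = 0
    for _, s in sessions.iterrows():
        for _ in range(int(s["n_tracks"])):
            r = 25_000.0 * np.sqrt(rng.uniform())
            az = rng.uniform(0.0, 360.0)
            x0 = r * np.sin(np.radians(az))
            y0 = r * np.cos(np.radians(az))
            th = np.radians(s["theta_b"])
            dx = s["v_g"] * duration_s * np.sin(th)
            dy = s["v_g"] * duration_s * np.cos(th)
            t0 = s["session_time"] + pd.to_timedelta(rng.uniform(0.0, 13.0), unit="min")
            alt0 = rng.normal(800.0, 120.0)
            rows.append({
                "track_id": tid,
                "t_start": t0, "t_end": t0 + pd.to_timedelta(duration_s, unit="s"),
                "lon_start": lon0 + x0 / m_lon, "lat_start": lat0 + y0 / m_lat,
                "lon_end": lon0 + (x0 + dx) / m_lon, "lat_end": lat0 + (y0 + dy) / m_lat,
                "alt_start": max(0.0, alt0), "alt_end": max(0.0, alt0 + rng.normal(0.0, 15.0)),
                "radar_speed": s["v_g"],
            })
            tid += 1
    return pd.DataFrame(rows)
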