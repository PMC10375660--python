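"""Per-track flight and wind parameters from the wind-triangle.

The bird's ground vector is the sum of its air vector and the wind vector.
All angles are geographic directions in degrees clockwise from true North;
wind directions use the "blowing towards" convention throughout (readers
convert "from"-convention station data by +180 deg).  Internally angles are
converted to radians and the E/N frame; differences are wrapped to
(-180, 180].

Sign conventions
----------------
* tailwind  W_t = W cos(theta_w - theta_m): positive when the wind pushes
  along the reference (goal) direction theta_m;
* crosswind W_c = W sin(theta_m - theta_w): positive when the wind pushes
  toward the bird's LEFT of the goal direction.  In this study's geometry
  (southward goal ~188 deg, eastward sea-breeze) the sea-breeze gives a
  positive crosswind.  Pass ``left_positive=False`` to flip.
* lateral component of airspeed (sideways speed)
  V_s = V_a sin(theta_b - theta_m), with theta_b the TRACK angle: zero
  under full drift compensation, positive when the track deviates
  clockwise of the goal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geo

#: mean migration direction of the radar dataset (deg); overridable everywhere
DEFAULT_GOAL_DIRECTION = 187.7

#: physically plausible airspeed ceiling for a soaring migrant (m/s)
AIRSPEED_CAP = 30.0


@dataclass(frozen=True)
class TrackRecord:
    """One radar-detected bird/flock segment (start/end of a ~1.5-min lock)."""

    track_id: int
    t_start: pd.Timestamp
    t_end: pd.Timestamp
    lon_start: float
    lat_start: float
    lon_end: float
    lat_end: float
    alt_start: float
    alt_end: float
    radar_speed: float | None = None

    def __post_init__(self):
        if self.t_end <= self.t_start:
            raise ValueError("track must have t_end > t_start")
        if abs(self.lat_start) > 90 or abs(self.lat_end) > 90:
            raise ValueError("latitude out of range")
        if self.alt_start < 0 or self.alt_end < 0:
            raise ValueError("altitudes must be >= 0")


def wrap_angle(delta_deg):
    """Wrap an angle difference (deg) to (-180, 180]."""
    d = -((-np.asarray(delta_deg, dtype=float) + 180.0) % 360.0 - 180.0)
    return d


def _to_en(speed, direction_deg):
    th = np.radians(np.asarray(direction_deg, dtype=float))
    s = np.asarray(speed, dtype=float)
    return s * np.sin(th), s * np.cos(th)


def track_angle_and_groundspeed(lon_start, lat_start, lon_end, lat_end, duration_s):
    """Track angle theta_b (deg) and groundspeed V_g (m/s) from endpoints.

    Returns ``(theta_b, v_g, undefined)`` where ``undefined`` flags
    zero-displacement tracks whose angle is meaningless (theta_b is NaN
    there, V_g is 0).  Horizontal distance and initial bearing come from
    the local tangent plane (see :mod:`seabreeze.geo`).
    """
    duration_s = np.asarray(duration_s, dtype=float)
    if np.any(duration_s <= 0):
        raise ValueError("track duration must be positive")
    theta_b, dist = geo.bearing_and_distance(lon_start, lat_start, lon_end, lat_end)
    v_g = dist / duration_s
    undefined = dist == 0.0
    theta_b = np.where(undefined, np.nan, theta_b)
    return theta_b, v_g, undefined


def airspeed(v_g, theta_b, wind_speed, wind_dir_towards):
    """Airspeed V_a = |ground vector - wind vector| (m/s)."""
    v_g = np.asarray(v_g, dtype=float)
    wind_speed = np.asarray(wind_speed, dtype=float)
    if np.any(v_g < 0) or np.any(wind_speed < 0):
        raise ValueError("speeds must be non-negative")
    ge, gn = _to_en(v_g, theta_b)
    we, wn = _to_en(wind_speed, wind_dir_towards)
    return np.hypot(ge - we, gn - wn)


def heading(v_g, theta_b, wind_speed, wind_dir_towards):
    """Heading (deg) of the air vector, for the heading-based sideways speed."""
    ge, gn = _to_en(v_g, theta_b)
    we, wn = _to_en(wind_speed, wind_dir_towards)
    return np.degrees(np.arctan2(ge - we, gn - wn)) % 360.0


def wind_components(wind_speed, wind_dir_towards, goal_direction=DEFAULT_GOAL_DIRECTION,
                    left_positive=True):
    """Tailwind and signed crosswind (m/s) relative to the goal direction."""
    w = np.asarray(wind_speed, dtype=float)
    d = np.radians(np.asarray(wind_dir_towards, dtype=float) - goal_direction)
    w_t = w * np.cos(d)
    w_c = -w * np.sin(d) if left_positive else w * np.sin(d)
    return w_t, w_c


def lateral_component_of_airspeed(v_a, theta_b, goal_direction=DEFAULT_GOAL_DIRECTION):
    """Sideways speed V_s = V_a sin(theta_b - theta_m), track-angle form."""
    d = np.radians(wrap_angle(np.asarray(theta_b, dtype=float) - goal_direction))
    return np.asarray(v_a, dtype=float) * np.sin(d)


def lateral_component_heading_based(v_a, heading_deg, goal_direction=DEFAULT_GOAL_DIRECTION):
    """Alternative sideways speed using the HEADING of the air vector.

    The track-angle form above follows the published formula; this variant
    measures the air vector's own lateral component and is provided for
    comparison only.
    """
    d = np.radians(wrap_angle(np.asarray(heading_deg, dtype=float) - goal_direction))
    return np.asarray(v_a, dtype=float) * np.sin(d)


def slope_angle(alt_gain_m, horizontal_dist_m):
    """Slope angle theta_s (deg) from altitude gain over horizontal distance."""
    return np.degrees(np.arctan2(np.asarray(alt_gain_m, dtype=float),
                                 np.asarray(horizontal_dist_m, dtype=float)))


def vertical_speed(v_g, theta_s_deg):
    """Signed climb rate V_g sin(theta_s) in m/s."""
    return np.asarray(v_g, dtype=float) * np.sin(np.radians(np.asarray(theta_s_deg, dtype=float)))


def daily_distance_km(speed_ms: float, hours: float) -> float:
    """Distance (km) covered at a sustained groundspeed over given hours."""
    return speed_ms * hours * 3600.0 / 1000.0


def compute_track_parameters(tracks: pd.DataFrame,
                             goal_direction: float | None = None,
                             coastline=None,
                             left_positive: bool = True) -> pd.DataFrame:
    """Annotate a track table (already wind-annotated) with flight parameters.

    Expects columns ``lon_start lat_start lon_end lat_end alt_start alt_end
    t_start t_end wind_speed wind_dir`` (wind in blowing-towards convention).
    If ``goal_direction`` is None it is the circular mean of all defined
    track angles — the way the study's 187.7 deg reference arises.
    """
    from .circular import circular_summary  # local import to avoid cycle

    df = tracks.copy()
    duration = (df["t_end"] - df["t_start"]).dt.total_seconds().to_numpy()
    theta_b, v_g, undefined = track_angle_and_groundspeed(
        df["lon_start"].to_numpy(), df["lat_start"].to_numpy(),
        df["lon_end"].to_numpy(), df["lat_end"].to_numpy(), duration)
    df["theta_b"], df["v_g"], df["theta_undefined"] = theta_b, v_g, undefined

    if goal_direction is None:
        goal_direction = circular_summary(theta_b[~np.isnan(theta_b)]).mean_direction
    df.attrs["goal_direction"] = float(goal_direction)

    df["v_a"] = airspeed(v_g, theta_b, df["wind_speed"].to_numpy(),
                         df["wind_dir"].to_numpy())
    df["heading"] = heading(v_g, theta_b, df["wind_speed"].to_numpy(),
                            df["wind_dir"].to_numpy())
    df["w_t"], df["w_c"] = wind_components(
        df["wind_speed"].to_numpy(), df["wind_dir"].to_numpy(),
        goal_direction, left_positive=left_positive)
    df["v_s"] = lateral_component_of_airspeed(df["v_a"].to_numpy(), theta_b, goal_direction)

    _, horiz = geo.bearing_and_distance(
        df["lon_start"].to_numpy(), df["lat_start"].to_numpy(),
        df["lon_end"].to_numpy(), df["lat_end"].to_numpy())
    theta_s = slope_angle((df["alt_end"] - df["alt_start"]).to_numpy(), horiz)
    df["theta_s"] = theta_s
    df["vertical_speed"] = vertical_speed(v_g, theta_s)

    if coastline is not None:
        df["distance_to_coast_km"] = geo.distance_to_polyline_km(
            df["lon_end"].to_numpy(), df["lat_end"].to_numpy(), coastline)
    return df
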