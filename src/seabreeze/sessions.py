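"""Track annotation, temporal filtering and 15-min session aggregation.

A *session* is the modelling unit: the average of all track parameters
over one ~15-min radar recording window, keyed by (year, ordinal date,
hours before sunset).  Aggregation uses arithmetic means for linear
quantities and the circular mean for the track angle.
"""

from __future__ import annotations

import datetime as dt
import logging

import numpy as np
import pandas as pd

from . import solar
from .circular import circular_mean

log = logging.getLogger(__name__)

#: Honey-buzzard migration season (month, day) inclusive bounds
SEASON_WINDOW = ((8, 16), (9, 30))

#: linear session-mean columns, aggregated arithmetically when present
LINEAR_COLUMNS = ["v_g", "v_a", "v_s", "w_t", "w_c", "vertical_speed",
                  "distance_to_coast_km", "wind_speed", "hours_before_sunset"]


def annotate_wind(tracks: pd.DataFrame, wind: pd.DataFrame,
                  max_gap_min: float = 30.0,
                  track_time_col: str = "t_start",
                  wind_time_col: str = "timestamp") -> pd.DataFrame:
    """Join each track to the wind record nearest in time.

    Ties are broken toward the earlier wind record; tracks farther than
    ``max_gap_min`` minutes from any record are dropped (count logged).
    """
    if len(wind) == 0:
        raise ValueError("empty wind series")
    wind = wind.sort_values(wind_time_col).reset_index(drop=True)
    tracks = tracks.sort_values(track_time_col).reset_index(drop=True)
    tt = tracks[track_time_col].to_numpy()
    wt = wind[wind_time_col].to_numpy()
    idx = np.searchsorted(wt, tt)
    idx_lo = np.clip(idx - 1, 0, len(wt) - 1)
    idx_hi = np.clip(idx, 0, len(wt) - 1)
    d_lo = np.abs(tt - wt[idx_lo])
    d_hi = np.abs(wt[idx_hi] - tt)
    nearest = np.where(d_lo <= d_hi, idx_lo, idx_hi)     # tie -> earlier record
    gap_min = np.minimum(d_lo, d_hi) / np.timedelta64(60, "s")
    keep = gap_min <= max_gap_min
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("annotate_wind: dropped %d/%d tracks with wind gap > %g min",
                 n_drop, len(tracks), max_gap_min)
    out = tracks.loc[keep].reset_index(drop=True)
    wsel = wind.iloc[nearest[keep]].reset_index(drop=True)
    out["wind_speed"] = wsel["wind_speed"].to_numpy()
    out["wind_dir"] = wsel["wind_dir"].to_numpy()
    out["wind_gap_min"] = gap_min[keep]
    out.attrs["n_dropped_wind_gap"] = n_drop
    return out


def temporal_filter(tracks: pd.DataFrame,
                    location: tuple[float, float] = solar.LATRUN,
                    season_window=SEASON_WINDOW,
                    diel_window: tuple[float, float] = (3.0, -3.0),
                    time_col: str = "t_start") -> pd.DataFrame:
    """Keep tracks in the seasonal and solar-relative diel windows.

    ``diel_window=(3, -3)`` keeps tracks from 3 h after sunrise to 3 h
    before sunset.  Adds the study's ``hours_before_sunset`` covariate
    (negative decimal hours) to the surviving tracks.
    """
    t = pd.DatetimeIndex(tracks[time_col])
    (m0, d0), (m1, d1) = season_window
    md = list(zip(t.month, t.day))
    in_season = np.array([(m0, d0) <= x <= (m1, d1) for x in md])
    sun = solar.hours_from_sun(t, *location)
    in_diel = (sun["hours_after_sunrise"].to_numpy() >= diel_window[0]) & \
              (sun["hours_before_sunset"].to_numpy() <= diel_window[1])
    keep = in_season & in_diel
    log.info("temporal_filter: kept %d/%d tracks (season %d, diel %d dropped)",
             int(keep.sum()), len(tracks), int((~in_season).sum()),
             int((in_season & ~in_diel).sum()))
    out = tracks.loc[keep].copy().reset_index(drop=True)
    out["hours_before_sunset"] = sun["hours_before_sunset"].to_numpy()[keep]
    out.attrs["n_dropped_temporal"] = int((~keep).sum())
    return out


def aggregate(tracks: pd.DataFrame, interval_min: float = 15.0,
              time_col: str = "t_start") -> pd.DataFrame:
    """Average track parameters into clock-aligned recording sessions.

    Linear quantities get arithmetic means, the track angle a circular
    mean.  Sessions are fixed ``interval_min`` bins of the track start
    times; empty bins produce no session.
    """
    if len(tracks) == 0:
        return pd.DataFrame()
    t = pd.DatetimeIndex(tracks[time_col])
    bins = t.floor(f"{int(interval_min)}min")
    df = tracks.copy()
    df["_session"] = bins
    rows = []
    for ts, g in df.groupby("_session", sort=True):
        row = {"session_time": ts,
               "year": ts.year,
               "ordinal_date": ts.timetuple().tm_yday,
               "n_tracks": len(g)}
        for c in LINEAR_COLUMNS:
            if c in g:
                row[c] = float(g[c].mean())
        if "theta_b" in g:
            row["theta_b"] = circular_mean(g["theta_b"].to_numpy())
        if "wind_dir" in g:
            row["wind_dir"] = circular_mean(g["wind_dir"].to_numpy())
        rows.append(row)
    out = pd.DataFrame(rows)
    assert int(out["n_tracks"].sum()) == len(tracks)
    return out
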