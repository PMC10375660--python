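"""Sunrise/sunset from the NOAA solar position equations.

Civil sunrise/sunset at zenith 90.833 deg (standard refraction + solar
radius), no site-specific refraction tuning.  Accuracy is about +-1 minute
at mid latitudes, ample for diel filtering of radar tracks.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

ZENITH_DEG = 90.833

#: radar site at Latrun, central Israel (lon, lat)
LATRUN = (34.978, 31.839)


def _solar_params(day_of_year: int, hour_utc: float, leap: bool):
    """Fractional-year solar declination (rad) and equation of time (min)."""
    denom = 366.0 if leap else 365.0
    g = 2.0 * np.pi / denom * (day_of_year - 1 + (hour_utc - 12.0) / 24.0)
    eqtime = 229.18 * (0.000075 + 0.001868 * np.cos(g) - 0.032077 * np.sin(g)
                       - 0.014615 * np.cos(2 * g) - 0.040849 * np.sin(2 * g))
    decl = (0.006918 - 0.399912 * np.cos(g) + 0.070257 * np.sin(g)
            - 0.006758 * np.cos(2 * g) + 0.000907 * np.sin(2 * g)
            - 0.002697 * np.cos(3 * g) + 0.00148 * np.sin(3 * g))
    return decl, eqtime


def sun_events_utc(date: dt.date, lon: float, lat: float):
    """(sunrise, sunset) as tz-aware UTC Timestamps for a calendar date."""
    doy = date.timetuple().tm_yday
    leap = date.year % 4 == 0 and (date.year % 100 != 0 or date.year % 400 == 0)
    lat_r = np.radians(lat)
    out = []
    for rise in (True, False):
        # iterate: hour angle depends weakly on the event time itself
        t_utc = 12.0 - lon / 15.0 + (-6.0 if rise else 6.0)
        for _ in range(3):
            decl, eqtime = _solar_params(doy, t_utc, leap)
            cos_ha = (np.cos(np.radians(ZENITH_DEG))
                      - np.sin(lat_r) * np.sin(decl)) / (np.cos(lat_r) * np.cos(decl))
            if not -1.0 <= cos_ha <= 1.0:
                raise ValueError("sun never rises/sets at this latitude and date")
            ha = np.degrees(np.arccos(cos_ha))
            minutes = 720.0 - 4.0 * (lon + (ha if rise else -ha)) - eqtime
            t_utc = minutes / 60.0
        out.append(pd.Timestamp(date, tz="UTC") + pd.Timedelta(minutes=minutes))
    return out[0], out[1]


def hours_from_sun(times: pd.Series | pd.DatetimeIndex, lon: float, lat: float) -> pd.DataFrame:
    """Hours after sunrise (>0) and before sunset (<0) for UTC timestamps.

    hours_before_sunset follows the study convention of negative decimal
    hours: -6.25 means six hours and fifteen minutes before local sunset.
    """
    t = pd.DatetimeIndex(times)
    if t.tz is None:
        raise ValueError("timestamps must be timezone-aware (UTC)")
    t = t.tz_convert("UTC")
    after_rise = np.empty(len(t))
    before_set = np.empty(len(t))
    cache: dict[dt.date, tuple] = {}
    for i, ts in enumerate(t):
        d = ts.date()
        if d not in cache:
            cache[d] = sun_events_utc(d, lon, lat)
        rise, sset = cache[d]
        after_rise[i] = (ts - rise).total_seconds() / 3600.0
        before_set[i] = (ts - sset).total_seconds() / 3600.0
    return pd.DataFrame(
        {"hours_after_sunrise": after_rise, "hours_before_sunset": before_set},
        index=t,
    )
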