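"""Readers, writers and pipeline configuration.

Column names in user files are never hard-coded: each reader takes a
mapping from canonical names to the file's own column names, configured
in the YAML pipeline config.  Wind files may use either direction
convention; "from"-convention directions are converted to the internal
blowing-towards convention by +180 degrees on read.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from shapely.geometry import shape
from shapely import wkt as shapely_wkt

from . import solar
from .synth import ConfigurationError

TRACK_COLUMNS = ["track_id", "t_start", "t_end", "lon_start", "lat_start",
                 "lon_end", "lat_end", "alt_start", "alt_end", "radar_speed"]
WIND_COLUMNS = ["timestamp", "wind_speed", "wind_dir"]


@dataclass
class SmootherSettings:
    k: int = 12
    ar_order: int = 2
    response: str = "v_a"


@dataclass
class DerivativeSettings:
    n_points: int = 1000
    n_sim: int = 10_000
    eps: float = 1e-7
    level: float = 0.95

    def __post_init__(self):
        if not (0 < self.level < 1):
            raise ConfigurationError("level must be in (0, 1)")
        if self.eps <= 0 or self.n_points < 2 or self.n_sim < 1:
            raise ConfigurationError("invalid derivative settings")


@dataclass
class PipelineConfig:
    tracks_path: str | None = None
    wind_path: str | None = None
    coastline_path: str | None = None
    scenario_path: str | None = None          # YAML scenario -> synthetic run
    output_dir: str = "seabreeze_run"
    timezone: str = "UTC"                     # civil timezone of file timestamps
    wind_convention: str = "towards"          # or "from"
    track_columns: dict = field(default_factory=dict)
    wind_columns: dict = field(default_factory=dict)
    goal_direction: float | None = None       # None -> circular mean of tracks
    session_interval_min: float = 15.0
    max_wind_gap_min: float = 30.0
    location: tuple = solar.LATRUN            # (lon, lat) of the radar
    smoother: SmootherSettings = field(default_factory=SmootherSettings)
    derivative: DerivativeSettings = field(default_factory=DerivativeSettings)
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "smoother" in kwargs:
            kwargs["smoother"] = _sub(SmootherSettings, kwargs["smoother"])
        if "derivative" in kwargs:
            kwargs["derivative"] = _sub(DerivativeSettings, kwargs["derivative"])
        if "location" in kwargs:
            kwargs["location"] = tuple(kwargs["location"])
        cfg = cls(**kwargs)
        if cfg.wind_convention not in ("towards", "from"):
            raise ConfigurationError("wind_convention must be 'towards' or 'from'")
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["location"] = list(self.location)
        return d


def _sub(cls, raw):
    if isinstance(raw, cls):
        return raw
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**raw)


def _apply_colmap(df: pd.DataFrame, canonical: list[str], colmap: dict, what: str,
                  optional=("radar_speed", "track_id")) -> pd.DataFrame:
    rename = {v: k for k, v in colmap.items()}
    df = df.rename(columns=rename)
    missing = [c for c in canonical if c not in df.columns and c not in optional]
    if missing:
        raise ConfigurationError(
            f"{what} file is missing mandatory columns {missing}; "
            f"available: {sorted(df.columns)} (map them via the config)")
    return df


def _parse_times(df: pd.DataFrame, cols, tz: str) -> tuple[pd.DataFrame, int]:
    bad = 0
    for c in cols:
        parsed = pd.to_datetime(df[c], errors="coerce", utc=False, format="mixed")
        if parsed.dt.tz is None:
            parsed = parsed.dt.tz_localize(tz)
        parsed = parsed.dt.tz_convert("UTC")
        bad += int(parsed.isna().sum())
        df[c] = parsed
    n0 = len(df)
    df = df.dropna(subset=list(cols)).reset_index(drop=True)
    return df, n0 - len(df)


def read_tracks(path, columns: dict | None = None, timezone: str = "UTC") -> pd.DataFrame:
    """Radar track CSV -> canonical track table (UTC timestamps)."""
    df = pd.read_csv(path)
    df = _apply_colmap(df, TRACK_COLUMNS, columns or {}, "track")
    df, n_bad = _parse_times(df, ["t_start", "t_end"], timezone)
    for c in ["lon_start", "lat_start", "lon_end", "lat_end", "alt_start", "alt_end"]:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    n0 = len(df)
    df = df.dropna(subset=["lon_start", "lat_start", "lon_end", "lat_end"]).reset_index(drop=True)
    if "track_id" not in df.columns:
        df["track_id"] = range(len(df))
    df.attrs["n_malformed"] = n_bad + (n0 - len(df))
    return df


def read_wind(path, columns: dict | None = None, convention: str = "towards",
              timezone: str = "UTC") -> pd.DataFrame:
    """Wind-station CSV -> canonical table in the blowing-towards convention."""
    df = pd.read_csv(path)
    df = _apply_colmap(df, WIND_COLUMNS, columns or {}, "wind")
    df, n_bad = _parse_times(df, ["timestamp"], timezone)
    df["wind_speed"] = pd.to_numeric(df["wind_speed"], errors="coerce")
    df["wind_dir"] = pd.to_numeric(df["wind_dir"], errors="coerce") % 360.0
    n0 = len(df)
    df = df.dropna(subset=["wind_speed", "wind_dir"]).reset_index(drop=True)
    if convention == "from":
        df["wind_dir"] = (df["wind_dir"] + 180.0) % 360.0
    elif convention != "towards":
        raise ConfigurationError("wind convention must be 'towards' or 'from'")
    df["convention"] = "towards"
    df.attrs["n_malformed"] = n_bad + (n0 - len(df))
    return df


def read_coastline(path):
    """Coastline polyline from a GeoJSON file or a WKT LineString file."""
    text = Path(path).read_text().strip()
    if text.upper().startswith("LINESTRING"):
        return shapely_wkt.loads(text)
    gj = json.loads(text)
    if gj.get("type") == "FeatureCollection":
        gj = gj["features"][0]["geometry"]
    elif gj.get("type") == "Feature":
        gj = gj["geometry"]
    geom = shape(gj)
    if geom.geom_type != "LineString":
        raise ConfigurationError(f"coastline must be a LineString, got {geom.geom_type}")
    return geom


def write_sessions(sessions: pd.DataFrame, path) -> None:
    sessions.to_csv(path, index=False, float_format="%.10g")


def read_sessions(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "session_time" in df.columns:
        df["session_time"] = pd.to_datetime(df["session_time"], format="mixed")
    return df
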