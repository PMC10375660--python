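"""End-to-end pipeline driver: simulate/read -> prepare -> fit -> derive -> report.

Every stage logs its input/output record counts into a run manifest that,
together with the config and seed, suffices to reproduce the run exactly.
Artifacts are plain CSV/JSON; the only binary output is a diagnostic
figure (excluded from the manifest hashes for that reason).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, derivative, io, kinematics, sessions, smoother, synth

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and counts so far."""

    def __init__(self, stage: str, counts: dict, cause: Exception):
        super().__init__(f"stage {stage!r} failed after counts {counts}: {cause}")
        self.stage, self.counts = stage, counts


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_scenarios(path):
    """WindScenario/BirdScenario pair from a YAML scenario file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - {"wind", "birds"}
    if unknown:
        raise synth.ConfigurationError(f"unknown scenario keys: {sorted(unknown)}")
    wind = synth.WindScenario(**(raw.get("wind") or {}))
    birds = synth.BirdScenario(**(raw.get("birds") or {}))
    return wind, birds


def prepare_sessions(cfg: io.PipelineConfig, counts: dict) -> pd.DataFrame:
    """Read/simulate inputs and produce the session table."""
    if cfg.scenario_path:
        wind_sc, birds = load_scenarios(cfg.scenario_path)
        sess = synth.simulate_study(wind_sc, birds, seed=cfg.seed)
        counts["sessions_simulated"] = len(sess)
        return sess
    if not cfg.tracks_path or not cfg.wind_path:
        raise synth.ConfigurationError(
            "config needs either scenario_path or tracks_path+wind_path")
    tracks = io.read_tracks(cfg.tracks_path, cfg.track_columns, cfg.timezone)
    counts["tracks_read"] = len(tracks)
    counts["tracks_malformed"] = tracks.attrs.get("n_malformed", 0)
    wind = io.read_wind(cfg.wind_path, cfg.wind_columns, cfg.wind_convention,
                        cfg.timezone)
    counts["wind_read"] = len(wind)
    tracks = sessions.temporal_filter(tracks, cfg.location)
    counts["tracks_after_temporal_filter"] = len(tracks)
    if len(tracks) == 0:
        raise synth.ConfigurationError("0 tracks after temporal filter")
    tracks = sessions.annotate_wind(tracks, wind, cfg.max_wind_gap_min)
    counts["tracks_after_wind_annotation"] = len(tracks)
    coast = io.read_coastline(cfg.coastline_path) if cfg.coastline_path else None
    tracks = kinematics.compute_track_parameters(
        tracks, goal_direction=cfg.goal_direction, coastline=coast)
    counts["goal_direction"] = tracks.attrs["goal_direction"]
    sess = sessions.aggregate(tracks, cfg.session_interval_min)
    counts["sessions"] = len(sess)
    return sess


def fit_smooth(sess: pd.DataFrame, cfg: io.PipelineConfig) -> smoother.SplineFit:
    s = cfg.smoother
    return smoother.fit(
        sess[s.response].to_numpy(), sess["hours_before_sunset"].to_numpy(),
        year=sess["year"].to_numpy() if "year" in sess else None,
        date=sess["ordinal_date"].to_numpy() if "ordinal_date" in sess else None,
        spec=smoother.SplineSpec(k=s.k), ar_order=s.ar_order)


def derive(fit: smoother.SplineFit, cfg: io.PipelineConfig) -> derivative.DerivativeResult:
    d = cfg.derivative
    return derivative.simultaneous_band(
        fit, n_points=d.n_points, n_sim=d.n_sim, level=d.level, eps=d.eps,
        seed=cfg.seed)


def report_figure(fit, result, sess, response: str, path: Path) -> None:
    """Two-panel diagnostic: fitted smooth with coloured significant spans,
    and the derivative with its simultaneous band (red increase, blue decrease)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xg = result.x
    fitted, se, _ = smoother.predict(fit, xg)
    fig, (ax0, ax1) = plt.subplots(2, 1, figsize=(7, 7), sharex=True)
    ax0.scatter(sess["hours_before_sunset"], sess[response], s=4, alpha=0.2,
                color="grey")
    ax0.plot(xg, fitted, color="black", lw=1.5)
    ax0.fill_between(xg, fitted - 1.96 * se, fitted + 1.96 * se, alpha=0.2,
                     color="grey")
    for seg in result.segments:
        m = (xg >= seg.x_start) & (xg <= seg.x_end)
        ax0.plot(xg[m], fitted[m], lw=3,
                 color="red" if seg.sign == "increase" else "blue")
    ax0.set_ylabel(response)
    ax1.axhline(0.0, color="grey", lw=0.8)
    ax1.plot(xg, result.derivative, color="black", lw=1.2)
    ax1.fill_between(xg, result.lower, result.upper, alpha=0.25, color="grey")
    ax1.set_xlabel("hours before sunset")
    ax1.set_ylabel(f"d {response} / d hour")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(cfg: io.PipelineConfig) -> Path:
    """Run all stages; returns the artifact directory."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    stage = "prepare"
    try:
        sess = prepare_sessions(cfg, counts)
        io.write_sessions(sess, out / "sessions.csv")
        stage = "fit"
        fit = fit_smooth(sess, cfg)
        (out / "fit.json").write_text(fit.to_json())
        stage = "derive"
        result = derive(fit, cfg)
        result.to_frame().to_csv(out / "derivative.csv", index=False,
                                 float_format="%.10g")
        result.segments_frame().to_csv(out / "segments.csv", index=False,
                                       float_format="%.10g")
        stage = "report"
        report_figure(fit, result, sess, cfg.smoother.response,
                      out / "diagnostics.png")
    except Exception as exc:                  # noqa: BLE001 - re-raise with context
        raise StageError(stage, counts, exc) from exc

    counts["edf_smooth"] = round(fit.edf_smooth, 4)
    counts["ar_phi"] = [round(v, 6) for v in fit.phi]
    counts["n_segments"] = len(result.segments)
    manifest = {
        "seabreeze_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "counts": counts,
        "artifacts": {p.name: _sha256(p)
                      for p in sorted(set(out.glob("*.csv")) | {out / "fit.json"})},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
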