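import numpy as np
import pandas as pd
import pytest

import seabreeze as sb
from seabreeze import synth


@pytest.fixture()
def rng():
    return np.random.default_rng(20160930)


@pytest.fixture(scope="session")
def noise_free_sessions():
    """Two noise-free days of the default scenario (exact wind triangle)."""
    birds = sb.BirdScenario(track_dir_concentration=None, session_noise_sd=0.0,
                            n_years=1, days_per_year=2)
    wind = sb.WindScenario(dir_noise_sd=0.0, speed_noise_sd=0.0)
    return sb.simulate_study(wind, birds, seed=7)


@pytest.fixture(scope="session")
def ar2_study():
    """Known smooth + AR(2) noise in the 7x20x28 nested layout."""
    rng = np.random.default_rng(42)
    h = np.linspace(-10, -3, 28)
    ys, xs, dates, years = [], [], [], []
    for yi in range(7):
        b = rng.normal(0, 0.2)
        for d in range(20):
            ys.append(16.5 - 0.1 * (h + 10) ** 2
                      + b + synth.ar2_noise(rng, 28, (0.5, 0.2), 0.5))
            xs.append(h)
            dates.append(np.full(28, yi * 1000 + d))
            years.append(np.full(28, 2005 + yi))
    return tuple(map(np.concatenate, (ys, xs, dates, years)))


@pytest.fixture(scope="session")
def small_fit():
    """A quick REML fit of a wiggly curve, reused by derivative tests."""
    rng = np.random.default_rng(3)
    x = np.repeat(np.linspace(-10, -3, 28), 6)
    y = np.sin(x) + rng.normal(0, 0.3, x.size)
    return sb.fit(y, x, ar_order=0)


def make_wind_frame(times, speeds, dirs):
    return pd.DataFrame({
        "timestamp": pd.DatetimeIndex(times, tz="UTC"),
        "wind_speed": np.asarray(speeds, dtype=float),
        "wind_dir": np.asarray(dirs, dtype=float),
        "convention": "towards",
    })
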