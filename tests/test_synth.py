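"""Synthetic sea-breeze generator: wind days, sessions, ground truth."""

import datetime as dt

import numpy as np
import pytest

import seabreeze as sb
from seabreeze import kinematics as kin, synth


class TestSimulateWindDay:
    def test_constant_direction_case(self):
        sc = sb.WindScenario(dir_start=90.0, dir_end=90.0, dir_noise_sd=0.0,
                             speed_noise_sd=0.0)
        wind = synth.simulate_wind_day(sc, dt.date(2015, 9, 1), seed=1)
        assert (wind["wind_dir"] == 90.0).all()

    def test_midpoint_of_shortest_arc(self):
        sc = sb.WindScenario(dir_noise_sd=0.0, speed_noise_sd=0.0)   # 87.1 -> 131.1
        assert sc.mean_direction(-6.5) == pytest.approx(109.1)

    def test_arc_crossing_north(self):
        sc = sb.WindScenario(dir_start=350.0, dir_end=10.0,
                             dir_noise_sd=0.0, speed_noise_sd=0.0)
        assert sc.mean_direction(-6.5) == pytest.approx(0.0)

    def test_flat_speed_scenario(self):
        sc = sb.WindScenario(speed_coefs=(4.1, 0.0, 0.0), dir_noise_sd=0.0,
                             speed_noise_sd=0.0)
        wind = synth.simulate_wind_day(sc, dt.date(2015, 9, 1), seed=1)
        np.testing.assert_allclose(wind["wind_speed"], 4.1)

    def test_window_and_interval(self):
        sc = sb.WindScenario()
        wind = synth.simulate_wind_day(sc, dt.date(2015, 9, 1), seed=1)
        h = wind["hours_before_sunset"]
        assert h.iloc[0] == -10.0 and h.iloc[-1] == -3.0
        assert len(wind) == 43                     # every 10 min over 7 h
        assert (wind["wind_speed"] >= 0).all()     # clipped at zero

    def test_bad_interval_rejected(self):
        with pytest.raises(synth.ConfigurationError, match="interval"):
            synth.simulate_wind_day(sb.WindScenario(sampling_interval=13.0),
                                    dt.date(2015, 9, 1), seed=1)

    def test_missing_seed_drawn_and_logged(self):
        with pytest.warns(UserWarning, match="seed"):
            synth.simulate_wind_day(sb.WindScenario(), dt.date(2015, 9, 1))


def _one_day_sessions(wind_dir, wind_speed, birds):
    """Sessions for a synthetic day with constant wind."""
    sc = sb.WindScenario(dir_start=wind_dir, dir_end=wind_dir,
                         speed_coefs=(wind_speed, 0.0, 0.0),
                         dir_noise_sd=0.0, speed_noise_sd=0.0)
    wind = synth.simulate_wind_day(sc, dt.date(2015, 9, 1), seed=3)
    return synth.simulate_sessions(wind, birds, seed=4)


class TestSimulateSessions:
    BIRDS = sb.BirdScenario(track_dir_concentration=None, session_noise_sd=0.0)

    def test_zero_wind_degenerate_triangle(self):
        s = _one_day_sessions(90.0, 0.0, self.BIRDS)
        np.testing.assert_allclose(s["v_g"], s["v_a"], atol=1e-12)
        np.testing.assert_allclose(s["theta_b"], 187.7, atol=1e-9)
        np.testing.assert_allclose(s["v_s"], 0.0, atol=1e-12)

    def test_pure_crosswind_full_compensation(self):
        """4 m/s pure crosswind at airspeed 16: heading offsets by
        arcsin(4/16) ~ 14.48 deg and the track stays on the goal."""
        birds = sb.BirdScenario(airspeed_base=16.0, airspeed_tailwind_slope=0.0,
                                track_dir_concentration=None, session_noise_sd=0.0)
        s = _one_day_sessions(187.7 - 90.0, 4.0, birds)   # wind from the right
        np.testing.assert_allclose(s["theta_b"], 187.7, atol=1e-9)
        offset = 187.7 - s["heading"].iloc[0]
        assert abs(offset) == pytest.approx(np.degrees(np.arcsin(4.0 / 16.0)),
                                            abs=1e-6)

    def test_pure_tailwind_airspeed_rule(self):
        birds = sb.BirdScenario(airspeed_base=17.0, airspeed_tailwind_slope=-1.0,
                                track_dir_concentration=None, session_noise_sd=0.0)
        s = _one_day_sessions(187.7, 4.0, birds)
        np.testing.assert_allclose(s["v_a"], 13.0, atol=1e-12)
        np.testing.assert_allclose(s["v_g"], 17.0, atol=1e-12)

    def test_drift_mode_deviates_by_triangle_angle(self):
        birds = sb.BirdScenario(compensation_mode="drift", airspeed_base=16.0,
                                airspeed_tailwind_slope=0.0,
                                track_dir_concentration=None, session_noise_sd=0.0)
        s = _one_day_sessions(187.7 - 90.0, 4.0, birds)
        # heading = goal; drift angle = atan2(W, Va) on the cross axis
        expected = np.degrees(np.arctan2(-4.0, 16.0))
        got = kin.wrap_angle(s["theta_b"].iloc[0] - 187.7)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_airspeed_cap_flags_truncation(self):
        birds = sb.BirdScenario(airspeed_base=29.0, airspeed_tailwind_slope=5.0,
                                track_dir_concentration=None, session_noise_sd=0.0)
        with pytest.warns(UserWarning, match="cap"):
            s = _one_day_sessions(187.7, 4.0, birds)
        assert s["truncated"].any()
        assert (s["v_a"] <= kin.AIRSPEED_CAP).all()


class TestRoundTrip:
    def test_kinematics_recovers_generator_truth(self, noise_free_sessions):
        """Applying the analysis kinematics to noise-free sessions must
        reproduce airspeed, wind components and sideways speed exactly."""
        s = noise_free_sessions
        v_a = kin.airspeed(s["v_g"], s["theta_b"], s["wind_speed"], s["wind_dir"])
        w_t, w_c = kin.wind_components(s["wind_speed"], s["wind_dir"], 187.7)
        v_s = kin.lateral_component_of_airspeed(v_a, s["theta_b"], 187.7)
        np.testing.assert_allclose(v_a, s["v_a"], atol=1e-9)
        np.testing.assert_allclose(w_t, s["w_t"], atol=1e-9)
        np.testing.assert_allclose(w_c, s["w_c"], atol=1e-9)
        np.testing.assert_allclose(v_s, s["v_s"], atol=1e-9)

    def test_full_compensation_means_zero_sideways(self, noise_free_sessions):
        np.testing.assert_allclose(noise_free_sessions["v_s"], 0.0, atol=1e-9)


class TestAR2Noise:
    def test_empirical_acf_matches_theory(self):
        """Lag-1/2 autocorrelation at 10,000 sessions within 0.05 of the
        values implied by (phi1, phi2)."""
        rng = np.random.default_rng(99)
        phi = (0.5, 0.2)
        e = synth.ar2_noise(rng, 10_000, phi, marginal_sd=1.0)
        rho1_t = phi[0] / (1 - phi[1])
        rho2_t = phi[0] * rho1_t + phi[1]
        c0 = e @ e / e.size
        assert (e[1:] @ e[:-1] / e.size) / c0 == pytest.approx(rho1_t, abs=0.05)
        assert (e[2:] @ e[:-2] / e.size) / c0 == pytest.approx(rho2_t, abs=0.05)
        assert np.std(e) == pytest.approx(1.0, abs=0.05)

    def test_nonstationary_coefs_rejected(self):
        with pytest.raises(synth.ConfigurationError, match="stationary"):
            sb.BirdScenario(ar_coefs=(0.9, 0.3))


class TestStudyStructure:
    def test_per_day_substreams_reproducible(self):
        birds = sb.BirdScenario(n_years=2, days_per_year=3)
        a = sb.simulate_study(bird_scenario=birds, seed=17)
        b = sb.simulate_study(bird_scenario=birds, seed=17)
        assert a.equals(b)

    def test_nesting_counts(self):
        birds = sb.BirdScenario(n_years=2, days_per_year=3, sessions_per_day=28)
        s = sb.simulate_study(bird_scenario=birds, seed=17)
        assert len(s) == 2 * 3 * 28
        assert s["year"].nunique() == 2
        assert s.groupby("year")["ordinal_date"].nunique().eq(3).all()

    def test_validation_counts(self):
        with pytest.raises(synth.ConfigurationError):
            sb.BirdScenario(n_years=0)
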