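"""Penalized-spline mixed-model engine: REML, AR(2), year intercepts."""

import subprocess
import sys

import numpy as np
import pytest

from seabreeze import smoother, synth
from seabreeze.smoother import SplineSpec, build_basis


class TestDegenerateSignals:
    def test_exactly_linear_data(self):
        """A linear signal must collapse to edf ~ 1 with the OLS slope."""
        x = np.linspace(-10, -3, 200)
        y = 2.0 + 0.44 * x
        f = smoother.fit(y, x, ar_order=0)
        assert f.edf_smooth == pytest.approx(1.0, abs=0.05)
        fitted, _ = smoother.predict(f, np.array([-9.0, -4.0]), se=False)
        slope = (fitted[1] - fitted[0]) / 5.0
        assert slope == pytest.approx(0.44, abs=1e-6)

    def test_constant_plus_white_noise_gives_zero_phi(self, rng):
        n = 500
        y = 7.0 + rng.standard_normal(n)
        x = np.tile(np.linspace(-10, -3, 25), 20)
        dates = np.repeat(np.arange(20), 25)
        f = smoother.fit(y, x, date=dates, ar_order=2)
        assert all(abs(p) < 0.1 for p in f.phi)


class TestAR2Estimation:
    def test_phi_recovered_in_nested_layout(self, ar2_study):
        y, x, dates, years = ar2_study
        f = smoother.fit(y, x, year=years, date=dates, ar_order=2)
        assert f.phi[0] == pytest.approx(0.5, abs=0.1)
        assert f.phi[1] == pytest.approx(0.2, abs=0.1)
        assert f.converged

    def test_year_variance_recovered(self, ar2_study):
        y, x, dates, years = ar2_study
        f = smoother.fit(y, x, year=years, date=dates, ar_order=2)
        assert 0.2**2 / 4 < f.sigma2_year < 0.2**2 * 4

    def test_whitening_beats_ols_under_correlation(self, rng):
        """GLS with estimated AR(2) tracks the true curve better than the
        independence fit when the data are a single long autocorrelated
        series — the regime where REML mistakes serial correlation for
        signal.  (With many independent replicate days the two point
        estimates coincide and neither systematically wins.)"""
        h = np.linspace(-10, -3, 112)
        truth = np.sin(h)
        wins = 0
        n_rep = 30
        for _ in range(n_rep):
            y = truth + synth.ar2_noise(rng, 112, (0.5, 0.2), 0.5)
            dates = np.zeros(112, dtype=int)
            f_gls = smoother.fit(y, h, date=dates, ar_order=2)
            f_ols = smoother.fit(y, h, ar_order=0)
            e_gls = smoother.predict(f_gls, h, se=False)[0] - truth
            e_ols = smoother.predict(f_ols, h, se=False)[0] - truth
            wins += float(e_gls @ e_gls) < float(e_ols @ e_ols)
        assert wins / n_rep >= 0.8


class TestREML:
    def test_ise_within_2x_of_best_fixed_lambda(self, rng):
        """REML's smoothing choice is near-oracle for a known smooth."""
        x = np.tile(np.linspace(-10, -3, 28), 6)
        truth = np.sin(x)
        lam_grid = 10.0 ** np.arange(-4, 4)
        ratios = []
        for _ in range(30):
            y = truth + rng.normal(0, 0.4, x.size)
            f = smoother.fit(y, x, ar_order=0)
            ise_reml = np.mean((smoother.predict(f, x, se=False)[0] - truth) ** 2)
            Xs, S, Z, _ = build_basis(x, SplineSpec())
            X = np.column_stack([np.ones(x.size), Xs])
            best = np.inf
            for lam in lam_grid:
                P = np.zeros((X.shape[1],) * 2)
                P[1:, 1:] = lam * S
                b = np.linalg.solve(X.T @ X + P, X.T @ y)
                best = min(best, np.mean((X @ b - truth) ** 2))
            ratios.append(ise_reml / best)
        assert np.mean(ratios) < 2.0

    def test_lambda_infinity_is_ols_line(self, rng):
        x = np.tile(np.linspace(-10, -3, 28), 4)
        y = np.sin(x) + rng.normal(0, 0.3, x.size)
        Xs, S, Z, _ = build_basis(x, SplineSpec())
        X = np.column_stack([np.ones(x.size), Xs])
        P = np.zeros((X.shape[1],) * 2)
        P[1:, 1:] = 1e8 * S
        b = np.linalg.solve(X.T @ X + P, X.T @ y)
        line = np.polyval(np.polyfit(x, y, 1), x)
        np.testing.assert_allclose(X @ b, line, atol=1e-4)


class TestEquivariance:
    def _data(self):
        rng = np.random.default_rng(5)
        x = np.tile(np.linspace(-10, -3, 28), 5)
        return x, np.sin(x) + rng.normal(0, 0.3, x.size)

    def test_x_shift(self):
        x, y = self._data()
        f0 = smoother.fit(y, x, ar_order=0)
        f1 = smoother.fit(y, x + 100.0, ar_order=0)
        g = np.linspace(-10, -3, 50)
        np.testing.assert_allclose(smoother.predict(f0, g, se=False)[0],
                                   smoother.predict(f1, g + 100.0, se=False)[0],
                                   atol=1e-6)

    def test_y_scale(self):
        x, y = self._data()
        f0 = smoother.fit(y, x, ar_order=0)
        f3 = smoother.fit(3.0 * y, x, ar_order=0)
        g = np.linspace(-10, -3, 50)
        np.testing.assert_allclose(3.0 * smoother.predict(f0, g, se=False)[0],
                                   smoother.predict(f3, g, se=False)[0],
                                   rtol=1e-4, atol=1e-6)


class TestPredict:
    def test_se_matches_quadratic_form_oracle(self, small_fit):
        g = np.linspace(-10, -3, 17)
        _, se, _ = smoother.predict(small_fit, g)
        rows = small_fit._curve_rows(g)
        ref = np.sqrt(np.diag(rows @ small_fit.covariance @ rows.T))
        np.testing.assert_allclose(se, ref, atol=1e-12)

    def test_extrapolation_flagged(self, small_fit):
        _, _, outside = smoother.predict(small_fit, np.array([-11.0, -5.0, 0.0]))
        assert outside.tolist() == [True, False, True]

    def test_serialization_round_trip(self, small_fit, tmp_path):
        p = tmp_path / "fit.json"
        p.write_text(small_fit.to_json())
        back = smoother.SplineFit.from_json(p.read_text())
        g = np.linspace(-10, -3, 33)
        np.testing.assert_allclose(smoother.predict(back, g, se=False)[0],
                                   smoother.predict(small_fit, g, se=False)[0],
                                   atol=1e-12)
        assert back.phi == small_fit.phi


class TestValidation:
    def test_ar_requires_dates(self):
        with pytest.raises(ValueError, match="date"):
            smoother.fit(np.zeros(50), np.linspace(0, 1, 50), ar_order=2)

    def test_edf_bounds(self, small_fit):
        assert 1.0 <= small_fit.edf_smooth <= small_fit.spec.k - 1


@pytest.mark.filterwarnings("ignore::RuntimeWarning")
def test_matches_mgcv_reference(tmp_path):
    """Same data into R mgcv (cr basis, REML): edf, fitted curve and the
    Bayesian covariance diagonal must agree closely."""
    rng = np.random.default_rng(77)
    x = np.repeat(np.linspace(-10, -3, 28), 10)
    y = np.sin(x) + rng.normal(0, 0.4, x.size)
    f = smoother.fit(y, x, ar_order=0)
    csv = tmp_path / "xy.csv"
    np.savetxt(csv, np.column_stack([x, y]), delimiter=",", header="x,y",
               comments="")
    out = tmp_path / "ref.csv"
    script = tmp_path / "ref.R"
    script.write_text(f'''
        d <- read.csv("{csv}")
        library(mgcv)
        m <- gam(y ~ s(x, k = 12, bs = "cr"), data = d, method = "REML")
        xg <- seq(-10, -3, length.out = 101)
        pr <- predict(m, data.frame(x = xg), se.fit = TRUE)
        cat(sum(m$edf), "\\n")
        write.csv(data.frame(fit = pr$fit, se = pr$se.fit), "{out}",
                  row.names = FALSE)
    ''')
    proc = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
    assert proc.returncode == 0, proc.stderr
    edf_r = float(proc.stdout.split()[0])
    assert f.edf == pytest.approx(edf_r, abs=0.05)
    ref = np.genfromtxt(out, delimiter=",", names=True)
    g = np.linspace(-10, -3, 101)
    fitted, se, _ = smoother.predict(f, g)
    np.testing.assert_allclose(fitted, ref["fit"], atol=5e-3)
    np.testing.assert_allclose(se, ref["se"], rtol=0.02)
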