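"""Rheological fitting: recovery, model comparison, agreement, bands."""

import numpy as np
import pytest
from scipy import optimize

import swelast as sw
from swelast.errors import ConfigError, FitFailureError

F_GRID = np.arange(200.0, 801.0, 50.0)


def kv_curve(mu, eta, noise_sigma=0.0, rng=None, f=F_GRID):
    med = sw.Medium(sw.KelvinVoigtParams(mu, eta))
    c = sw.phase_velocity(med, 2 * np.pi * f)
    if noise_sigma:
        c = c * (1.0 + rng.normal(0.0, noise_sigma, c.size))
    return sw.DispersionCurve(f=f, c=c)


class TestFitDispersion:
    def test_noiseless_kv_exact_recovery(self):
        fit = sw.fit_dispersion(kv_curve(1512.0, 0.536), "kelvin_voigt")
        assert fit.params.mu == pytest.approx(1512.0, rel=1e-3)
        assert fit.params.eta == pytest.approx(0.536, rel=1e-3)
        assert fit.r_squared > 0.9999
        assert not fit.flagged

    def test_flat_curve_elastic_limit(self):
        c = np.full(F_GRID.size, 1.3)
        curve = sw.DispersionCurve(f=F_GRID, c=c)
        fit = sw.fit_dispersion(curve, "kelvin_voigt")
        assert fit.params.mu == pytest.approx(1690.0, rel=1e-6)
        assert fit.params.eta < 1e-6

    def test_four_point_liver_refit_matches_oracle(self):
        # velocities implied by the imaging-branch liver moduli at the four
        # acquisition frequencies; oracle = independent Nelder-Mead
        # refinement of the same velocity-space objective from the elastic
        # starting guess
        f4 = np.array([200.0, 400.0, 600.0, 800.0])
        c4 = np.sqrt(np.array([1.32, 2.82, 3.69, 4.84]))
        curve = sw.DispersionCurve(f=f4, c=c4)
        fit = sw.fit_dispersion(curve, "kelvin_voigt")

        w4 = 2 * np.pi * f4

        def sse(p):
            mu, eta = p
            if mu <= 0 or eta < 0:
                return 1e9
            g = mu + 1j * w4 * eta
            c_m = w4 / np.real(w4 * np.sqrt(1000.0 / g))
            return float(np.sum((c_m - c4) ** 2))

        start = [1000.0 * np.mean(c4) ** 2, 0.5]
        oracle = optimize.minimize(sse, start, method="Nelder-Mead",
                                   options=dict(xatol=1e-10, fatol=1e-14))
        assert fit.params.mu == pytest.approx(oracle.x[0], rel=1e-4)
        assert fit.params.eta == pytest.approx(oracle.x[1], rel=1e-4)
        # frozen oracle values: the viscous-liver neighbourhood
        assert fit.params.mu == pytest.approx(986.79, rel=1e-3)
        assert fit.params.eta == pytest.approx(0.62798, rel=1e-3)

    def test_parameter_recovery_ensemble(self):
        rng = np.random.default_rng(99)
        mu_err, eta_err = [], []
        for _ in range(50):
            mu = rng.uniform(500.0, 5000.0)
            eta = rng.uniform(0.1, 1.0)
            fit = sw.fit_dispersion(kv_curve(mu, eta, 0.02, rng),
                                    "kelvin_voigt")
            mu_err.append(abs(fit.params.mu - mu) / mu)
            eta_err.append(abs(fit.params.eta - eta) / eta)
        assert np.median(mu_err) < 0.05
        assert np.median(eta_err) < 0.15

    def test_r2_one_iff_zero_residuals_and_decreasing_with_noise(self):
        rng = np.random.default_rng(3)
        fit0 = sw.fit_dispersion(kv_curve(1000.0, 0.5), "kelvin_voigt")
        assert fit0.r_squared == pytest.approx(1.0, abs=1e-9)
        means = []
        for sigma in (0.005, 0.02, 0.08):
            r2s = [sw.fit_dispersion(kv_curve(1000.0, 0.5, sigma, rng),
                                     "kelvin_voigt").r_squared
                   for _ in range(20)]
            means.append(np.mean(r2s))
        assert means[0] > means[1] > means[2]

    def test_ci95_contains_estimate(self):
        rng = np.random.default_rng(11)
        fit = sw.fit_dispersion(kv_curve(1500.0, 0.4, 0.02, rng))
        lo, hi = fit.ci95["mu"]
        assert lo <= fit.params.mu <= hi
        lo, hi = fit.ci95["eta"]
        assert lo <= fit.params.eta <= hi

    def test_maxwell_fit_on_maxwell_data(self):
        med = sw.Medium(sw.MaxwellParams(2000.0, 1.2))
        c = sw.phase_velocity(med, 2 * np.pi * F_GRID)
        fit = sw.fit_dispersion(sw.DispersionCurve(f=F_GRID, c=c), "maxwell")
        assert fit.params.mu1 == pytest.approx(2000.0, rel=1e-3)
        assert fit.params.mu2 == pytest.approx(1.2, rel=1e-3)

    def test_flat_curve_maxwell_flagged_wide(self):
        c = np.full(F_GRID.size, 1.3)
        fit = sw.fit_dispersion(sw.DispersionCurve(f=F_GRID, c=c), "maxwell")
        assert fit.flagged or fit.ci95["mu1"][1] - fit.ci95["mu1"][0] > \
            10.0 * fit.params.mu1

    def test_too_few_points_rejected(self):
        curve = sw.DispersionCurve(f=np.array([300.0]), c=np.array([1.2]))
        with pytest.raises(ConfigError):
            sw.fit_dispersion(curve)

    def test_unknown_model_rejected(self):
        with pytest.raises(ConfigError):
            sw.fit_dispersion(kv_curve(1000.0, 0.5), "zener")


class TestModelSelection:
    def test_kv_beats_maxwell_on_kv_data(self):
        rng = np.random.default_rng(1234)
        wins = 0
        n = 40
        for _ in range(n):
            mu = rng.uniform(500.0, 5000.0)
            eta = rng.uniform(0.1, 1.0)
            curve = kv_curve(mu, eta, 0.02, rng)
            r2_kv = sw.fit_dispersion(curve, "kelvin_voigt").r_squared
            r2_m = sw.fit_dispersion(curve, "maxwell").r_squared
            wins += r2_kv >= r2_m
        assert wins / n >= 0.95


class TestModuliByFrequency:
    def test_table_style_conversion(self):
        curve = sw.DispersionCurve(f=np.array([200.0, 800.0]),
                                   c=np.array([1.30, 2.00]))
        out = sw.moduli_by_frequency(curve, 1000.0)
        np.testing.assert_allclose(out["mu_kpa"], [1.69, 4.00])

    def test_hydrogel_endpoints(self):
        curve = sw.DispersionCurve(f=np.array([200.0, 800.0]),
                                   c=np.array([0.79, 0.93]))
        out = sw.moduli_by_frequency(curve, 1000.0)
        np.testing.assert_allclose(out["mu_kpa"], [0.6241, 0.8649])

    def test_monotone_on_kv_curve(self):
        out = sw.moduli_by_frequency(kv_curve(1000.0, 0.6), 1000.0)
        assert np.all(np.diff(out["mu_kpa"]) >= 0)


class TestPearsonAgreement:
    def test_identical_curves(self):
        curve = kv_curve(1500.0, 0.5)
        r, pairs = sw.pearson_agreement(curve, curve)
        assert r == pytest.approx(1.0)
        assert pairs.shape == (len(curve), 2)

    def test_negated_trend(self):
        curve = kv_curve(1500.0, 0.5)
        flipped = sw.DispersionCurve(f=curve.f, c=curve.c[::-1].copy())
        r, _ = sw.pearson_agreement(curve, flipped)
        assert r == pytest.approx(-1.0, abs=0.05)

    def test_offset_grids_still_agree(self):
        a = kv_curve(1500.0, 0.5, f=np.arange(200.0, 801.0, 50.0))
        b = kv_curve(1500.0, 0.5, f=np.arange(210.0, 811.0, 50.0))
        r, pairs = sw.pearson_agreement(a, b, freq_tol_hz=25.0)
        assert r > 0.999
        assert pairs.shape[0] >= 12

    def test_insufficient_overlap_rejected(self):
        a = kv_curve(1500.0, 0.5, f=np.array([200.0, 250.0, 300.0]))
        b = kv_curve(1500.0, 0.5, f=np.array([700.0, 750.0, 800.0]))
        with pytest.raises(ConfigError):
            sw.pearson_agreement(a, b)


class TestConfidenceBand:
    def test_noiseless_band_collapses(self):
        curve = kv_curve(1200.0, 0.4)
        fit = sw.fit_dispersion(curve)
        band = sw.confidence_band(fit, curve, n_boot=50, seed=0)
        assert np.max(band.hi - band.lo) < 1e-6

    def test_known_noise_band_covers_truth(self):
        rng = np.random.default_rng(7)
        covered = []
        truth = sw.phase_velocity(
            sw.Medium(sw.KelvinVoigtParams(1500.0, 0.5)), 2 * np.pi * F_GRID)
        for s in range(30):
            c = truth + rng.normal(0.0, 0.05, truth.size)
            curve = sw.DispersionCurve(f=F_GRID, c=c)
            fit = sw.fit_dispersion(curve)
            band = sw.confidence_band(fit, curve, n_boot=200, seed=s)
            covered.append(np.mean((truth >= band.lo) & (truth <= band.hi)))
        assert np.mean(covered) >= 0.90

    def test_same_seed_identical_bands(self):
        rng = np.random.default_rng(2)
        curve = kv_curve(1000.0, 0.6, 0.03, rng)
        fit = sw.fit_dispersion(curve)
        b1 = sw.confidence_band(fit, curve, n_boot=100, seed=5)
        b2 = sw.confidence_band(fit, curve, n_boot=100, seed=5)
        np.testing.assert_array_equal(b1.lo, b2.lo)
        np.testing.assert_array_equal(b1.hi, b2.hi)
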