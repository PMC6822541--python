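"""Seasonal sinusoidal model: augmentation, fitting, Bayesian R2 and
prediction bands."""

import datetime as dt

import numpy as np
import pytest

from finhorm.data import Dataset, Hormone, HormoneRecord, Sex
from finhorm.mcmc import ChainConfig, PosteriorSamples
from finhorm.seasonal import (
    PERIOD,
    SeasonalFit,
    augment_winter_replication,
    bayesian_r2,
    fit_seasonal,
    predict_band,
)
from finhorm.synthetic import SeasonalSimParams, gen_seasonal_concentrations

LIGHT = ChainConfig(3, 6000, 0.1, 3, seed=2)


def _rec(day, conc=1.0, wid=None):
    date = dt.date(2015, 1, 1) + dt.timedelta(days=day - 1)
    return HormoneRecord(wid or f"M{day:03d}", Sex.MALE, Hormone.TESTOSTERONE,
                         conc, date)


class TestWinterReplication:
    def test_winter_record_duplicated_a_year_later(self):
        ds = Dataset([_rec(40)])
        aug = augment_winter_replication(ds, (1, 90))
        assert sorted(r.day_of_year for r in aug) == [40, 405]
        assert [r.replicated for r in sorted(aug, key=lambda r: r.day_of_year)] \
            == [False, True]

    def test_non_winter_record_untouched(self):
        ds = Dataset([_rec(200)])
        aug = augment_winter_replication(ds, (1, 90))
        assert len(aug) == 1 and not aug.records[0].replicated

    def test_mixed_set_counts(self):
        days = [10, 45, 88, 120, 150, 200, 220, 250, 280, 300]
        aug = augment_winter_replication(Dataset([_rec(d) for d in days]), (1, 90))
        assert len(aug) == 13
        assert sum(r.replicated for r in aug) == 3

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            augment_winter_replication(Dataset([_rec(40)]), (0, 400))


class TestFitSeasonal:
    def test_strong_signal_recovery(self, seasonal_recovery_fit):
        # generating truth: amplitude 1.0, peak day 227, sigma 0.7
        _, _, fit = seasonal_recovery_fit
        assert fit.p_positive_amplitude == 1.0
        assert abs(fit.peak_day_median - 227.0) <= 15
        amp_lo, amp_hi = np.percentile(fit.amplitude, [2.5, 97.5])
        assert amp_lo < 1.0 < amp_hi

    def test_noiseless_cosine_interpolation(self):
        alpha, amp, peak = 0.2, 0.8, 227.0
        days = [46, 100, 137, 227, 318]
        recs = [_rec(d, float(np.exp(alpha + amp * np.cos(
            2 * np.pi * (d - peak) / 365)))) for d in days]
        fit = fit_seasonal(Dataset(recs), LIGHT)
        assert np.median(fit.alpha) == pytest.approx(alpha, abs=0.02)
        assert np.median(fit.amplitude) == pytest.approx(amp, abs=0.02)
        assert fit.peak_day_median == pytest.approx(peak, abs=2.0)

    def test_identical_days_rejected(self):
        recs = [_rec(100, c, wid=f"M{i}") for i, c in
                enumerate((1.0, 2.0, 1.5, 0.5, 1.2))]
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_seasonal(Dataset(recs), LIGHT)

    def test_sign_phase_symmetry_of_the_curve(self):
        # (A, phi) and (-A, phi + half period) trace the same curve
        days = np.arange(1.0, 366.0)
        cfg = ChainConfig(2, 10, 0.0, 1, seed=0)

        def fit_with(amp, phi):
            s = PosteriorSamples({
                "alpha": np.full((2, 10), 0.1),
                "amplitude": np.full((2, 10), amp),
                "phi": np.full((2, 10), phi),
                "log_sigma": np.full((2, 10), np.log(0.5)),
            }, cfg)
            return SeasonalFit(s, days=days, log_conc=np.zeros_like(days),
                               weights=np.ones_like(days))

        c1 = fit_with(0.9, 227.0).curve(days)
        c2 = fit_with(-0.9, (227.0 + PERIOD / 2) % PERIOD).curve(days)
        assert np.allclose(c1, c2)

    def test_replication_equivalence(self):
        """Fitting winter-augmented data equals fitting the original
        data with winter likelihood contributions doubled (the model is
        365-periodic)."""
        ds = gen_seasonal_concentrations(
            SeasonalSimParams(n=60, amplitude=0.8, peak_day=227.0, sigma=0.6,
                              day_range=(10, 300), seed=6))
        aug = augment_winter_replication(ds, (1, 90))
        cfg = ChainConfig(3, 10_000, 0.1, 3, seed=3)
        fit_aug = fit_seasonal(aug, cfg)
        w = np.where(ds.days <= 90, 2.0, 1.0)
        fit_w = fit_seasonal(ds, cfg, weights=w)
        assert fit_aug.alpha.mean() == pytest.approx(fit_w.alpha.mean(), abs=0.05)
        assert fit_aug.amplitude.mean() == pytest.approx(fit_w.amplitude.mean(),
                                                         abs=0.05)
        assert np.median(fit_aug.sigma) == pytest.approx(np.median(fit_w.sigma),
                                                         abs=0.05)


class TestBayesianR2:
    def test_noiseless_limit_is_one(self):
        alpha, amp, peak = 0.2, 0.8, 227.0
        days = [46, 100, 137, 227, 318]
        recs = [_rec(d, float(np.exp(alpha + amp * np.cos(
            2 * np.pi * (d - peak) / 365)))) for d in days]
        fit = fit_seasonal(Dataset(recs), LIGHT)
        assert bayesian_r2(fit)["mean"] > 0.99

    def test_flat_draw_gives_zero(self):
        days = np.array([50.0, 150.0, 250.0, 350.0])
        cfg = ChainConfig(2, 10, 0.0, 1, seed=0)
        s = PosteriorSamples({
            "alpha": np.full((2, 10), 0.3),
            "amplitude": np.zeros((2, 10)),
            "phi": np.full((2, 10), 100.0),
            "log_sigma": np.full((2, 10), np.log(0.5)),
        }, cfg)
        fit = SeasonalFit(s, days=days, log_conc=np.zeros_like(days),
                          weights=np.ones_like(days))
        assert np.all(bayesian_r2(fit)["draws"] == 0.0)

    def test_known_variance_ratio(self):
        # signal:total variance 1:4 -> BR2 = 0.25; amplitude a over a
        # full uniform year has signal variance a^2/2
        sigma = 0.6
        a = np.sqrt(2 * sigma**2 / 3)
        ds = gen_seasonal_concentrations(
            SeasonalSimParams(n=500, amplitude=a, peak_day=200.0, sigma=sigma,
                              day_range=(1, 365), seed=9))
        fit = fit_seasonal(ds, ChainConfig(3, 8000, 0.1, 4, seed=4))
        assert bayesian_r2(fit)["mean"] == pytest.approx(0.25, abs=0.05)


class TestPredictBand:
    def test_periodicity(self, seasonal_recovery_fit):
        _, _, fit = seasonal_recovery_fit
        b1 = predict_band(fit, np.array([10.0, 100.0]))
        b2 = predict_band(fit, np.array([375.0, 465.0]))
        assert np.allclose(b1.mean, b2.mean)
        assert np.allclose(b1.band95[0], b2.band95[0])

    def test_point_mass_posterior_zero_width(self):
        days = np.arange(1.0, 366.0, 30.0)
        cfg = ChainConfig(2, 10, 0.0, 1, seed=0)
        s = PosteriorSamples({
            "alpha": np.full((2, 10), 0.1),
            "amplitude": np.full((2, 10), 0.5),
            "phi": np.full((2, 10), 227.0),
            "log_sigma": np.full((2, 10), np.log(0.5)),
        }, cfg)
        fit = SeasonalFit(s, days=days, log_conc=np.zeros_like(days),
                          weights=np.ones_like(days))
        band = predict_band(fit, days)
        assert np.allclose(band.band95[0], band.band95[1])
        assert np.allclose(band.mean, band.band75[0])

    def test_bands_nested_and_peak_in_late_summer(self, seasonal_recovery_fit):
        _, _, fit = seasonal_recovery_fit
        band = predict_band(fit)
        assert np.all(band.band75[0] >= band.band95[0] - 1e-12)
        assert np.all(band.band75[1] <= band.band95[1] + 1e-12)
        # generating peak day 227 (mid August); August spans days 213-243
        assert 213 <= band.peak_day_of_mean_curve <= 243

    def test_empty_grid_rejected(self, seasonal_recovery_fit):
        _, _, fit = seasonal_recovery_fit
        with pytest.raises(ValueError):
            predict_band(fit, np.array([]))
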