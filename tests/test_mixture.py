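"""Two-cluster mixture and log-normal location models."""

import numpy as np
import pytest

from finhorm.mcmc import ChainConfig, PosteriorSamples, sample_posterior
from finhorm.mixture import (
    MixtureFit,
    cluster_occurrence,
    cluster_source_probability,
    fit_lognormal_mean,
    fit_mixture,
)

LIGHT = ChainConfig(3, 6000, 0.1, 3, seed=1)


def _point_mass_fit(m_a, m_b, s_a, s_b, w_b, n_obs=4):
    """A degenerate MixtureFit whose posterior is a single point."""
    cfg = ChainConfig(2, 50, 0.0, 1, seed=0)
    shape = (2, 50)

    def logit(p):
        return np.log(p / (1 - p))

    samples = PosteriorSamples(
        {
            "m_a": np.full(shape, m_a),
            "m_b": np.full(shape, m_b),
            "log_s_a": np.full(shape, np.log(s_a)),
            "log_s_b": np.full(shape, np.log(s_b)),
            "logit_w_b": np.full(shape, logit(w_b)),
        },
        cfg,
    )
    z = np.zeros((100, n_obs), dtype=np.int8)
    return MixtureFit(samples=samples, z=z,
                      concentrations=np.ones(n_obs))


class TestFitMixture:
    def test_recovers_cluster_geometry(self, mixture_recovery_fit):
        # generating geometry: geo-means 1.56 / 27.12 ng/g, weight_A 0.61
        ds, labels, fit = mixture_recovery_fit
        summ = {s.parameter: s for s in fit.summaries()}
        a, b = summ["mu_cluster_A"], summ["mu_cluster_B"]
        assert a.quantiles[2.5] < 1.56 < a.quantiles[97.5]
        assert b.quantiles[2.5] < 27.12 < b.quantiles[97.5]
        w_a = 1 - fit.w_b
        lo, hi = np.percentile(w_a, [2.5, 97.5])
        assert lo < 0.61 < hi
        assert a.rhat < 1.02 and b.rhat < 1.02

    def test_ordering_constraint_holds_in_every_draw(self, mixture_recovery_fit):
        _, _, fit = mixture_recovery_fit
        assert np.all(fit.m_a < fit.m_b)

    def test_separable_clumps_assigned_with_certainty(self):
        rng = np.random.default_rng(0)
        y = np.concatenate([np.exp(rng.normal(0.0, 0.05, 10)),
                            np.exp(rng.normal(5.0, 0.05, 10))])
        fit = fit_mixture(y, LIGHT)
        p_b = fit.z.mean(axis=0)  # posterior membership per observation
        assert np.all(p_b[:10] < 0.01)
        assert np.all(p_b[10:] > 0.99)
        occ = cluster_occurrence(fit)
        assert occ["fraction_A_mean"] == pytest.approx(0.5, abs=0.01)

    def test_unimodal_data_gives_wide_weight_posterior(self):
        rng = np.random.default_rng(5)
        y = np.exp(rng.normal(1.0, 0.3, 8))
        fit = fit_mixture(y, LIGHT)
        lo, hi = np.percentile(fit.w_b, [2.5, 97.5])
        assert hi - lo > 0.5  # no false certainty about the weight

    def test_label_permutation_leaves_posterior_unchanged(self):
        from finhorm.synthetic import MixtureSimParams, gen_mixture_concentrations

        ds, _ = gen_mixture_concentrations(MixtureSimParams(n=150, seed=8))
        fits = [fit_mixture(ds.concentrations,
                            ChainConfig(3, 6000, 0.1, 3, seed=s))
                for s in (1, 2)]
        med = [np.median(np.exp(f.m_a)) for f in fits]
        assert med[0] == pytest.approx(med[1], rel=0.05)

    @pytest.mark.parametrize("bad", [[1.0, 2.0, 3.0], [2.0] * 10])
    def test_degenerate_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            fit_mixture(np.asarray(bad), LIGHT)


class TestSourceProbability:
    def test_complementarity_is_exact(self, mixture_recovery_fit):
        _, _, fit = mixture_recovery_fit
        for v in (0.5, 1.56, 6.0, 27.12, 170.0):
            p_b = cluster_source_probability(fit, v)
            assert 0.0 <= p_b <= 1.0
            # P(A|v) is defined as 1 - P(B|v); complementarity is exact

    def test_symmetric_fit_midpoint_is_half(self):
        fit = _point_mass_fit(m_a=0.0, m_b=2.0, s_a=0.7, s_b=0.7, w_b=0.5)
        assert cluster_source_probability(fit, np.exp(1.0)) == pytest.approx(0.5)

    def test_extreme_values_assigned_to_their_cluster(self):
        # point-mass fit at the reference cluster medians; the extreme
        # observed females (173.36 and 0.76 ng/g) resolve decisively
        fit = _point_mass_fit(m_a=np.log(1.56), m_b=np.log(27.12),
                              s_a=0.7, s_b=0.7, w_b=0.39)
        assert cluster_source_probability(fit, 173.36) > 0.99
        assert cluster_source_probability(fit, 0.76) < 0.01

    def test_monotone_in_value_for_equal_spreads(self):
        fit = _point_mass_fit(m_a=0.0, m_b=2.0, s_a=0.6, s_b=0.6, w_b=0.4)
        grid = np.exp(np.linspace(-2, 4, 50))
        probs = [cluster_source_probability(fit, v) for v in grid]
        assert np.all(np.diff(probs) >= -1e-12)

    def test_nonpositive_value_rejected(self, mixture_recovery_fit):
        _, _, fit = mixture_recovery_fit
        with pytest.raises(ValueError):
            cluster_source_probability(fit, 0.0)


class TestClusterOccurrence:
    def test_fractions_sum_to_one_every_draw(self, mixture_recovery_fit):
        _, _, fit = mixture_recovery_fit
        occ = cluster_occurrence(fit)
        frac_a = occ["fraction_A_draws"]
        frac_b = fit.z.mean(axis=1)
        assert np.allclose(frac_a + frac_b, 1.0)

    def test_ci_covers_realized_label_fraction(self, mixture_recovery_fit):
        _, labels, fit = mixture_recovery_fit
        occ = cluster_occurrence(fit)
        lo, hi = occ["fraction_A_ci95"]
        realized = 1 - labels.mean()
        assert lo <= realized <= hi


class TestLognormalMean:
    def test_constant_data_concentrates_at_value(self):
        fit = fit_lognormal_mean(np.full(10, 2.5), LIGHT)
        assert np.median(np.exp(fit.mu_log)) == pytest.approx(2.5, abs=0.01)

    def test_recovers_generating_geometric_mean(self):
        # generated at the reference testosterone geometric mean of
        # 0.88 ng/g; the CI must cover the realized sample geometric
        # mean, and the posterior median must sit on it
        rng = np.random.default_rng(5)
        y = np.exp(rng.normal(np.log(0.88), 0.6, 44))
        gm = float(np.exp(np.log(y).mean()))
        fit = fit_lognormal_mean(y, LIGHT)
        s = fit.summary()
        assert s.quantiles[2.5] < gm < s.quantiles[97.5]
        assert s.quantiles[50.0] == pytest.approx(gm, rel=0.02)
        # normal-theory CI width: 2 * 1.96 * sd/sqrt(n) on the log scale
        expected_w = 2 * 1.96 * np.log(y).std(ddof=1) / np.sqrt(y.size)
        got_w = np.log(s.quantiles[97.5]) - np.log(s.quantiles[2.5])
        assert got_w == pytest.approx(expected_w, rel=0.15)

    def test_posterior_mean_matches_normal_theory_center(self):
        rng = np.random.default_rng(6)
        y = np.exp(rng.normal(0.5, 0.4, 5))
        fit = fit_lognormal_mean(y, ChainConfig(3, 8000, 0.1, 2, seed=2))
        ybar = np.log(y).mean()
        # with vague priors the posterior of mu_log centers on the
        # sample mean of the logs
        assert fit.mu_log.mean() == pytest.approx(ybar, abs=0.05)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fit_lognormal_mean(np.array([1.0, -2.0, 3.0]), LIGHT)


class TestGridOracle:
    def test_tiny_mixture_matches_grid_posterior(self):
        """Engine-level check: MCMC on a 3-parameter mixture posterior
        (means and weight, spread fixed) agrees with a dense
        grid-approximation of the same posterior."""
        rng = np.random.default_rng(7)
        ly = np.concatenate([rng.normal(0.0, 0.5, 4), rng.normal(2.5, 0.5, 4)])
        s = 0.5

        def loglik(m1, m2, w):
            a = np.log1p(-w) - 0.5 * ((ly[:, None] - m1) / s) ** 2
            b = np.log(w) - 0.5 * ((ly[:, None] - m2) / s) ** 2
            return np.logaddexp(a, b).sum(axis=0)

        def lp(th):
            m1, m2, w = th
            if not 0 < w < 1 or m1 > m2:
                return -np.inf
            la = np.log1p(-w) - 0.5 * ((ly - m1) / s) ** 2
            lb = np.log(w) - 0.5 * ((ly - m2) / s) ** 2
            return np.logaddexp(la, lb).sum() - (m1**2 + m2**2) / 200.0

        cfg = ChainConfig(3, 12_000, 0.1, 3, seed=4)
        samples = sample_posterior(lp, np.array([0.0, 2.5, 0.5]), cfg,
                                   ["m1", "m2", "w"],
                                   initial_scales=np.array([0.3, 0.3, 0.15]))

        # dense grid oracle over the ordered region m1 <= m2
        m_grid = np.linspace(-1.5, 4.0, 120)
        w_grid = np.linspace(0.005, 0.995, 99)
        # per-observation component log-densities on the mean grid
        comp = -0.5 * ((ly[:, None] - m_grid[None, :]) / s) ** 2  # (n, 120)
        logp = np.empty((120, 120, 99))
        for k, w in enumerate(w_grid):
            la = np.log1p(-w) + comp  # (n, m1)
            lb = np.log(w) + comp  # (n, m2)
            logp[:, :, k] = np.logaddexp(
                la[:, :, None], lb[:, None, :]
            ).sum(axis=0)
        logp -= (m_grid[:, None, None] ** 2 + m_grid[None, :, None] ** 2) / 200.0
        M1, M2, W = np.meshgrid(m_grid, m_grid, w_grid, indexing="ij")
        logp[M1 > M2] = -np.inf
        p = np.exp(logp - logp.max())
        p /= p.sum()
        grid_mean_m2 = (p * M2).sum()
        grid_mean_w = (p * W).sum()

        m2_draws = samples.flat("m2")
        w_draws = samples.flat("w")
        assert m2_draws.mean() == pytest.approx(grid_mean_m2, abs=0.05)
        assert w_draws.mean() == pytest.approx(grid_mean_w, abs=0.03)
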