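"""Bayesian models for hormone concentration distributions.

Two models, both with log-normal likelihoods:

* a two-component normal mixture on log progesterone concentrations,
  testing the bimodal structure (cluster A: low values, resting or
  lactating females; cluster B: high values, luteal-phase or pregnant
  females) and yielding per-animal cluster membership;
* a simple Bayesian estimate of the mean for log testosterone.

Cluster labels are made identifiable by per-draw relabelling so that
the cluster-A mean is always the smaller one; mixture weights and
spreads swap along with the means, which leaves every label-invariant
posterior quantity unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mcmc import (
    ChainConfig,
    PosteriorSamples,
    PosteriorSummary,
    TEST_SCALE,
    sample_posterior,
    summarize,
)

__all__ = [
    "MixturePriors",
    "MixtureFit",
    "LocationFit",
    "fit_mixture",
    "cluster_source_probability",
    "cluster_occurrence",
    "fit_lognormal_mean",
]

_LOG_SQRT_2PI = 0.5 * np.log(2 * np.pi)


def _norm_logpdf(x, mu, sd):
    return -_LOG_SQRT_2PI - np.log(sd) - 0.5 * ((x - mu) / sd) ** 2


@dataclass(frozen=True)
class MixturePriors:
    """Vague default priors for the mixture and location models.

    Cluster means: Normal(0, mean_sd^2) on the log scale; spreads:
    Half-Normal(sd_scale); mixing weight: Uniform(0, 1).
    """

    mean_sd: float = 10.0
    sd_scale: float = 5.0


@dataclass
class MixtureFit:
    """Posterior draws of the two-cluster log-normal mixture.

    ``m_a, m_b`` are cluster means on the natural-log ng/g scale
    (``m_a < m_b`` in every retained draw), ``s_a, s_b`` the log-scale
    spreads, ``w_b`` the mixing weight of cluster B, and ``z`` the
    per-female cluster-indicator draws (n_draws x n_obs, 1 = cluster B).
    """

    samples: PosteriorSamples
    z: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.m_a >= self.m_b):
            raise ValueError("identifiability violated: m_a must be < m_b in "
                             "every retained draw")

    @property
    def m_a(self) -> np.ndarray:
        return self.samples.flat("m_a")

    @property
    def m_b(self) -> np.ndarray:
        return self.samples.flat("m_b")

    @property
    def s_a(self) -> np.ndarray:
        return np.exp(self.samples.flat("log_s_a"))

    @property
    def s_b(self) -> np.ndarray:
        return np.exp(self.samples.flat("log_s_b"))

    @property
    def w_b(self) -> np.ndarray:
        from scipy.special import expit

        return expit(self.samples.flat("logit_w_b"))

    def summaries(self) -> list[PosteriorSummary]:
        """Cluster-center summaries on the ng/g scale (exponentiated)."""
        out = [
            summarize(self.samples, "m_a", transform=np.exp),
            summarize(self.samples, "m_b", transform=np.exp),
        ]
        return [
            PosteriorSummary("mu_cluster_A", out[0].mean, out[0].sd,
                             out[0].quantiles, out[0].rhat, out[0].neff_percent),
            PosteriorSummary("mu_cluster_B", out[1].mean, out[1].sd,
                             out[1].quantiles, out[1].rhat, out[1].neff_percent),
        ]


@dataclass
class LocationFit:
    """Posterior draws of the log-normal location model."""

    samples: PosteriorSamples

    @property
    def mu_log(self) -> np.ndarray:
        return self.samples.flat("mu_log")

    @property
    def sigma_log(self) -> np.ndarray:
        return np.exp(self.samples.flat("log_sigma"))

    def summary(self, name: str = "mu") -> PosteriorSummary:
        s = summarize(self.samples, "mu_log", transform=np.exp)
        return PosteriorSummary(name, s.mean, s.sd, s.quantiles, s.rhat,
                                s.neff_percent)


def fit_mixture(
    concentrations,
    config: ChainConfig = TEST_SCALE,
    priors: MixturePriors | None = None,
) -> MixtureFit:
    """Fit the two-component normal mixture to log concentrations.

    The likelihood marginalises the cluster indicators:
    ``log y_i ~ (1 - w_b) N(m_a, s_a) + w_b N(m_b, s_b)``.  Sampling is
    over ``(m_a, m_b, log s_a, log s_b, logit w_b)``; retained draws are
    relabelled so ``m_a < m_b``.  Indicator draws ``z_i`` are then
    simulated from their exact conditional (the responsibilities) for
    each retained parameter draw.

    Parameters
    ----------
    concentrations
        Positive hormone concentrations, ng/g.  At least 4 values, not
        all identical.
    config, priors
        Chain layout and (optionally) prior scales.
    """
    y = np.asarray(concentrations, dtype=float)
    if y.size < 4:
        raise ValueError("need at least 4 observations to fit a 2-component mixture")
    if np.any(y <= 0):
        raise ValueError("all concentrations must be positive")
    ly = np.log(y)
    if np.ptp(ly) == 0:
        raise ValueError("all observations identical: mixture is degenerate")
    pri = priors or MixturePriors()
    v_mean = pri.mean_sd**2

    def log_post(theta: np.ndarray) -> float:
        m1, m2, ls1, ls2, lw = theta
        if abs(ls1) > 30 or abs(ls2) > 30 or abs(lw) > 30:
            return -np.inf
        s1, s2 = np.exp(ls1), np.exp(ls2)
        # logistic transform of the weight, with Jacobian
        log_wb = -np.log1p(np.exp(-lw))
        log_wa = -np.log1p(np.exp(lw))
        comp = np.logaddexp(
            log_wa + _norm_logpdf(ly, m1, s1),
            log_wb + _norm_logpdf(ly, m2, s2),
        )
        loglik = comp.sum()
        logprior = (
            -(m1**2 + m2**2) / (2 * v_mean)
            - (s1**2 + s2**2) / (2 * pri.sd_scale**2) + ls1 + ls2
            + log_wa + log_wb  # Uniform(0,1) weight via logit Jacobian
        )
        return loglik + logprior

    # moment-based starting point: split at the midpoint of the log range
    cut = 0.5 * (ly.min() + ly.max())
    low, high = ly[ly <= cut], ly[ly > cut]
    if low.size == 0 or high.size == 0:
        med = np.median(ly)
        low, high = ly[ly <= med], ly[ly > med]
    if high.size == 0:  # all values at the median
        low, high = ly[: ly.size // 2], ly[ly.size // 2:]
    m10, m20 = low.mean(), high.mean()
    s10 = max(low.std(), 0.1 * max(ly.std(), 0.1))
    s20 = max(high.std(), 0.1 * max(ly.std(), 0.1))
    w0 = np.clip(high.size / ly.size, 0.05, 0.95)
    init = np.array([m10, m20, np.log(s10), np.log(s20), np.log(w0 / (1 - w0))])
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x6D78)))
    inits = init + rng.normal(0, 0.05, size=(config.n_chains, 5))

    samples = sample_posterior(
        log_post,
        inits,
        config,
        param_names=["m_a", "m_b", "log_s_a", "log_s_b", "logit_w_b"],
        initial_scales=np.array([0.2, 0.2, 0.2, 0.2, 0.4]),
    )

    # per-draw relabelling to the canonical order m_a < m_b
    m1, m2 = samples.draws["m_a"], samples.draws["m_b"]
    swap = m1 > m2
    for a_name, b_name in (("m_a", "m_b"), ("log_s_a", "log_s_b")):
        a, b = samples.draws[a_name], samples.draws[b_name]
        a_sw, b_sw = np.where(swap, b, a), np.where(swap, a, b)
        samples.draws[a_name], samples.draws[b_name] = a_sw, b_sw
    lw = samples.draws["logit_w_b"]
    samples.draws["logit_w_b"] = np.where(swap, -lw, lw)

    z = _draw_indicators(samples, ly, seed=config.seed)
    return MixtureFit(samples=samples, z=z, concentrations=y)


def _responsibilities(samples: PosteriorSamples, ly: np.ndarray) -> np.ndarray:
    """P(z_i = B | theta_draw, y_i) for every retained draw and obs."""
    from scipy.special import expit

    m_a = samples.flat("m_a")[:, None]
    m_b = samples.flat("m_b")[:, None]
    s_a = np.exp(samples.flat("log_s_a"))[:, None]
    s_b = np.exp(samples.flat("log_s_b"))[:, None]
    w_b = expit(samples.flat("logit_w_b"))[:, None]
    la = np.log1p(-np.clip(w_b, 1e-300, 1 - 1e-16)) + _norm_logpdf(ly[None, :], m_a, s_a)
    lb = np.log(np.clip(w_b, 1e-300, None)) + _norm_logpdf(ly[None, :], m_b, s_b)
    return np.exp(lb - np.logaddexp(la, lb))


def _draw_indicators(samples: PosteriorSamples, ly: np.ndarray, seed: int) -> np.ndarray:
    resp = _responsibilities(samples, ly)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x7A)))
    return (rng.random(resp.shape) < resp).astype(np.int8)


def cluster_source_probability(fit: MixtureFit, value: float) -> float:
    """Posterior probability that a concentration came from cluster B.

    Averages, over the retained draws, the responsibility
    ``w_b N(log v | m_b, s_b) / [w_b N(log v | m_b, s_b) +
    (1 - w_b) N(log v | m_a, s_a)]``.  ``P(A | v) = 1 - P(B | v)``
    exactly.
    """
    if not value > 0:
        raise ValueError("value must be positive")
    lv = np.array([np.log(value)])
    return float(_responsibilities(fit.samples, lv).mean())


def cluster_occurrence(fit: MixtureFit) -> dict[str, object]:
    """Posterior of the fraction of sampled females in each cluster.

    Per retained draw, ``fraction_A = mean(z_i == A)``; the two
    fractions sum to one in every draw.  Returns posterior means and
    95% credible intervals plus the raw per-draw fractions.
    """
    frac_b = fit.z.mean(axis=1)
    frac_a = 1.0 - frac_b
    lo_a, hi_a = np.percentile(frac_a, [2.5, 97.5])
    return {
        "fraction_A_mean": float(frac_a.mean()),
        "fraction_A_ci95": (float(lo_a), float(hi_a)),
        "fraction_B_mean": float(frac_b.mean()),
        "fraction_B_ci95": (float(1 - hi_a), float(1 - lo_a)),
        "fraction_A_draws": frac_a,
    }


def fit_lognormal_mean(
    concentrations,
    config: ChainConfig = TEST_SCALE,
    priors: MixturePriors | None = None,
) -> LocationFit:
    """Simple Bayesian estimation of the mean of log concentrations.

    ``log y_i ~ N(mu_log, sigma_log)`` with vague priors; summaries are
    reported as ``exp(mu_log)`` (the geometric mean, ng/g).
    """
    y = np.asarray(concentrations, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    if np.any(y <= 0):
        raise ValueError("all concentrations must be positive")
    ly = np.log(y)
    pri = priors or MixturePriors()
    n = ly.size

    def log_post(theta: np.ndarray) -> float:
        mu, ls = theta
        if abs(ls) > 30:
            return -np.inf
        sigma = np.exp(ls)
        loglik = -n * ls - 0.5 * np.sum((ly - mu) ** 2) / sigma**2
        logprior = -mu**2 / (2 * pri.mean_sd**2) - sigma**2 / (2 * pri.sd_scale**2) + ls
        return loglik + logprior

    s0 = max(float(ly.std()), 1e-3)
    init = np.array([float(ly.mean()), np.log(s0)])
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x4C)))
    inits = init + rng.normal(0, 0.02, size=(config.n_chains, 2))
    samples = sample_posterior(
        log_post,
        inits,
        config,
        param_names=["mu_log", "log_sigma"],
        initial_scales=np.array([s0 / np.sqrt(n), 0.2]),
    )
    return LocationFit(samples=samples)
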