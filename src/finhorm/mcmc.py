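"""Posterior sampling machinery shared by all models.

The sampler is an adaptive random-walk Metropolis scheme updating one
coordinate at a time (Metropolis-within-Gibbs).  Proposal scales adapt
toward a ~44% per-coordinate acceptance rate, but only during the
discarded burn-in prefix, so the retained chain is a valid Markov chain
with the target as its stationary distribution.  The contract is
correctness of the stationary distribution, not any particular kernel.

Convergence diagnostics (split-chain Gelman-Rubin R-hat, autocorrelation
based effective sample size) are delegated to :mod:`arviz`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "ChainConfig",
    "PosteriorSamples",
    "PosteriorSummary",
    "retained_sample_count",
    "sample_posterior",
    "gelman_rubin",
    "effective_sample_size",
    "summarize",
    "REFERENCE_SCALE",
    "TEST_SCALE",
]

_QUANTILES = (2.5, 25.0, 50.0, 75.0, 97.5)


@dataclass(frozen=True)
class ChainConfig:
    """MCMC run specification.

    Parameters
    ----------
    n_chains
        Number of independent chains (>= 1).
    n_iterations
        Iterations per chain, counting the burn-in prefix.
    burn_in_fraction
        Fraction of iterations discarded as adaptation/burn-in
        (0 <= f < 1).  Burn-in is removed before thinning.
    thin
        Keep one of every ``thin`` post-burn-in iterations.
    seed
        Root seed; per-chain streams are spawned from it.
    """

    n_chains: int = 3
    n_iterations: int = 20_000
    burn_in_fraction: float = 0.10
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0 <= self.burn_in_fraction < 1:
            raise ValueError("burn_in_fraction must lie in [0, 1)")
        if self.n_iterations < self.thin:
            raise ValueError("n_iterations must be >= thin")

    @property
    def retained_per_chain(self) -> int:
        return int(
            np.floor(self.n_iterations * (1.0 - self.burn_in_fraction) / self.thin)
        )


#: The configuration the reference analysis ran at: 3 chains of one
#: million iterations, 10% burn-in, keeping one of every 20 states,
#: for 135,000 retained draws in total.
REFERENCE_SCALE = ChainConfig(n_chains=3, n_iterations=1_000_000,
                          burn_in_fraction=0.10, thin=20)

#: Default desk-scale configuration used throughout the test-suite.
TEST_SCALE = ChainConfig(n_chains=3, n_iterations=20_000,
                         burn_in_fraction=0.10, thin=5)


def retained_sample_count(config: ChainConfig) -> int:
    """Total retained posterior draws across chains.

    ``n_chains * floor(n_iterations * (1 - burn_in_fraction) / thin)``.
    """
    return config.n_chains * config.retained_per_chain


@dataclass
class PosteriorSamples:
    """Retained draws from one or more chains.

    ``draws`` maps parameter name -> array of shape (n_chains, n_retained).
    """

    draws: dict[str, np.ndarray]
    config: ChainConfig
    accept_rate: np.ndarray | None = None

    def __post_init__(self) -> None:
        expected = self.config.retained_per_chain
        for name, arr in self.draws.items():
            if arr.ndim != 2:
                raise ValueError(f"draws for {name!r} must be 2-D (chain, draw)")
            if arr.shape != (self.config.n_chains, expected):
                raise ValueError(
                    f"draws for {name!r} have shape {arr.shape}, expected "
                    f"({self.config.n_chains}, {expected})"
                )

    @property
    def parameters(self) -> list[str]:
        return list(self.draws)

    @property
    def n_retained(self) -> int:
        return self.config.n_chains * self.config.retained_per_chain

    def flat(self, parameter: str) -> np.ndarray:
        """All retained draws of one parameter, chains concatenated."""
        return self.draws[parameter].reshape(-1)

    def stacked(self) -> np.ndarray:
        """Draws as an array of shape (n_chains, n_retained, n_params)."""
        return np.stack([self.draws[p] for p in self.parameters], axis=-1)


@dataclass(frozen=True)
class PosteriorSummary:
    """One row of a posterior summary table.

    Quantiles are the 2.5/25/50/75/97.5 empirical percentiles.
    ``neff_percent`` is the effective sample size as a percentage of the
    retained draws, capped at 100.
    """

    parameter: str
    mean: float
    sd: float
    quantiles: Mapping[float, float]
    rhat: float
    neff_percent: float

    def __post_init__(self) -> None:
        qs = [self.quantiles[q] for q in _QUANTILES]
        if any(b < a - 1e-12 for a, b in zip(qs, qs[1:])):
            raise ValueError("quantiles must be nondecreasing")


def _chain_rngs(config: ChainConfig) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(config.seed)
    return [np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(config.n_chains)]


def sample_posterior(
    log_posterior: Callable[[np.ndarray], float],
    init: np.ndarray | Sequence[Sequence[float]],
    config: ChainConfig,
    param_names: Sequence[str] | None = None,
    initial_scales: np.ndarray | None = None,
) -> PosteriorSamples:
    """Draw from an unnormalised log-posterior by adaptive random-walk
    Metropolis.

    Parameters
    ----------
    log_posterior
        Maps a parameter vector to the unnormalised log posterior
        density.  Must be finite at every initial point; ``-inf`` is the
        conventional return for points outside the support.
    init
        Either one vector (replicated to every chain) or an array of
        shape (n_chains, d) of per-chain starting points.
    config
        Chain layout; the retained-draw count obeys
        :func:`retained_sample_count` exactly.
    param_names
        Names for the ``d`` coordinates; defaults to ``p0..p{d-1}``.
    initial_scales
        Starting proposal standard deviations per coordinate.

    Notes
    -----
    The kept iterations are the last ``retained_per_chain * thin``
    states of each chain, subsampled every ``thin`` states; adaptation
    stops before the first kept state.
    """
    init = np.atleast_2d(np.asarray(init, dtype=float))
    if init.shape[0] == 1 and config.n_chains > 1:
        init = np.repeat(init, config.n_chains, axis=0)
    if init.shape[0] != config.n_chains:
        raise ValueError("init must supply one vector or one per chain")
    d = init.shape[1]
    names = list(param_names) if param_names is not None else [f"p{i}" for i in range(d)]
    if len(names) != d:
        raise ValueError("param_names length must match parameter dimension")

    r = config.retained_per_chain
    n = config.n_iterations
    # first kept state; everything before it is the adaptive prefix
    first_keep = n - r * config.thin + config.thin - 1
    adapt_until = max(first_keep, 1)

    out = np.empty((config.n_chains, r, d))
    acc_rates = np.empty((config.n_chains, d))
    rngs = _chain_rngs(config)

    for c, rng in enumerate(rngs):
        x = init[c].copy()
        lp = float(log_posterior(x))
        if not np.isfinite(lp):
            raise ValueError(
                f"log_posterior is not finite at the chain-{c} initial point"
            )
        scales = (np.ones(d) * 0.5 if initial_scales is None
                  else np.asarray(initial_scales, dtype=float).copy())
        acc = np.zeros(d)
        acc_window = np.zeros(d)
        accepted_any = False
        k = 0
        for i in range(n):
            adapting = i < adapt_until
            for j in range(d):
                step = scales[j] * rng.standard_normal()
                xj = x[j]
                x[j] = xj + step
                lp_new = float(log_posterior(x))
                if np.log(rng.random()) < lp_new - lp:
                    lp = lp_new
                    acc[j] += 1
                    acc_window[j] += 1
                    accepted_any = True
                else:
                    x[j] = xj
            if adapting and (i + 1) % 50 == 0:
                rate = acc_window / 50.0
                scales *= np.exp(np.clip(rate - 0.44, -0.5, 0.5))
                acc_window[:] = 0
            if i >= first_keep and (i - first_keep) % config.thin == 0:
                out[c, k] = x
                k += 1
        if not accepted_any:
            warnings.warn(
                f"chain {c}: every proposal was rejected; the chain never moved",
                RuntimeWarning,
            )
        acc_rates[c] = acc / n

    draws = {name: out[:, :, j].copy() for j, name in enumerate(names)}
    return PosteriorSamples(draws=draws, config=config, accept_rate=acc_rates)


def _as_float(arviz_result) -> float:
    import numpy as _np

    try:
        return float(_np.asarray(arviz_result["x"]))
    except (KeyError, IndexError, TypeError):
        return float(_np.asarray(arviz_result))


def _chain_matrix(samples: PosteriorSamples, parameter: str) -> np.ndarray:
    arr = samples.draws[parameter]
    if arr.shape[0] < 2:
        raise ValueError(
            "convergence diagnostics need at least 2 chains; run the model "
            "with n_chains >= 2"
        )
    if arr.shape[1] < 10:
        raise ValueError("need at least 10 retained draws per chain")
    return arr


def gelman_rubin(samples: PosteriorSamples, parameter: str) -> float:
    """Split-chain potential scale reduction factor (R-hat).

    Approximately 1 at convergence; values above ~1.01 indicate the
    chains have not mixed.  Chains with zero variance (a constant
    parameter) return 1 by convention.
    """
    import arviz as az

    arr = _chain_matrix(samples, parameter)
    if np.ptp(arr) == 0:
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = _as_float(az.rhat(arr, method="split"))
    if not np.isfinite(rhat):
        return 1.0
    # the PSRF estimator can dip below 1 by sampling noise; 1 is its floor
    return max(1.0, float(rhat))


def effective_sample_size(samples: PosteriorSamples, parameter: str) -> tuple[float, float]:
    """Autocorrelation-based ESS and its percentage of retained draws.

    Returns ``(neff, neff_percent)``.  Antithetic chains can produce a
    nominal ESS above the retained count; both values are capped so that
    ``neff <= retained`` and ``neff_percent <= 100``.
    """
    import arviz as az

    arr = _chain_matrix(samples, parameter)
    total = arr.size
    if np.ptp(arr) == 0:
        return float(total), 100.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        neff = _as_float(az.ess(arr, method="mean"))
    if not np.isfinite(neff) or neff < 0:
        neff = float(total)
    neff = min(float(neff), float(total))
    return neff, 100.0 * neff / total


def summarize(
    samples: PosteriorSamples,
    parameter: str,
    transform: Callable[[np.ndarray], np.ndarray] | None = None,
) -> PosteriorSummary:
    """Posterior summary of ``transform(draws)`` for one parameter.

    The transform (default identity) is applied draw-wise before any
    statistic, so for a monotone map the quantile columns commute with
    it: ``quantile(exp(draws), q) == exp(quantile(draws, q))``.  The SD
    column is the standard deviation of the *transformed* draws.
    Diagnostics (R-hat, ESS) are computed on the untransformed chains
    and are reported as NaN for single-chain runs.
    """
    arr = samples.draws[parameter]
    if arr.size < 10:
        raise ValueError("need at least 10 draws to summarize")
    t = transform(arr) if transform is not None else arr
    flat = np.asarray(t, dtype=float).reshape(-1)
    # order-statistic quantiles (no interpolation), so quantiles commute
    # exactly with monotone transforms of the draws
    qs = np.percentile(flat, _QUANTILES, method="inverted_cdf")
    if samples.config.n_chains >= 2:
        rhat = gelman_rubin(samples, parameter)
        _, neff_pct = effective_sample_size(samples, parameter)
    else:
        rhat, neff_pct = float("nan"), float("nan")
    return PosteriorSummary(
        parameter=parameter,
        mean=float(flat.mean()),
        sd=float(flat.std(ddof=1)),
        quantiles=dict(zip(_QUANTILES, (float(q) for q in qs))),
        rhat=rhat,
        neff_percent=neff_pct,
    )
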