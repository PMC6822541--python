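"""Assay quality-control rules and validation statistics.

Implements the plate-level decision rules of the enzyme-immunoassay
workflow — duplicate coefficient of variation (rerun above 10%), the
50–3200 pg/mL working range (inclusive bounds) — and the validation
statistics: per-spike recovery efficiency, the Bayesian accuracy
regression (measured vs added mass; a slope far from 1 indicates over-
or under-estimation), and the parallelism comparison of a pooled
serial-dilution response against the standard curve.

The CV threshold is applied to back-calculated concentrations, and
parallelism is assessed on a linearised response versus
log-concentration, with parallelism declared when the 95% credible
interval of the slope difference contains zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .data import AssayMeasurement
from .mcmc import ChainConfig, PosteriorSamples, TEST_SCALE, sample_posterior

__all__ = [
    "RangeStatus",
    "QCResult",
    "ValidationResult",
    "ParallelismResult",
    "CV_RERUN_THRESHOLD",
    "ASSAY_RANGE_PG_ML",
    "duplicate_cv",
    "range_check",
    "recovery_efficiency",
    "accuracy_test",
    "parallelism_test",
]

#: Duplicates with a CV above this percentage trigger a rerun.
CV_RERUN_THRESHOLD = 10.0

#: Working range of the assay in pg/mL, bounds inclusive.
ASSAY_RANGE_PG_ML = (50.0, 3200.0)


class RangeStatus(str, Enum):
    IN_RANGE = "in_range"
    BELOW_RANGE = "below_range"
    ABOVE_RANGE = "above_range"


@dataclass(frozen=True)
class QCResult:
    sample_id: str
    cv_percent: float
    rerun_flag: bool
    range_status: RangeStatus


@dataclass(frozen=True)
class ValidationResult:
    """Accuracy-regression outcome.

    ``slope`` and ``intercept`` are posterior medians; ``br2`` is the
    posterior-mean Bayesian R-squared (fitted-variance over fitted-plus-
    residual variance, per draw).
    """

    slope: float
    slope_ci95: tuple[float, float]
    intercept: float
    br2: float
    br2_ci95: tuple[float, float]
    interpretation: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.br2 <= 1.0:
            raise ValueError("br2 must lie in [0, 1]")
        for lo, hi in (self.slope_ci95, self.br2_ci95):
            if lo > hi:
                raise ValueError("interval bounds must be ordered")


@dataclass(frozen=True)
class ParallelismResult:
    parallel: bool
    slope_difference: float
    slope_difference_ci95: tuple[float, float]
    slope_standard: float
    slope_dilution: float


def duplicate_cv(measurement: AssayMeasurement) -> QCResult:
    """Duplicate-CV rerun rule plus the working-range check.

    CV% is 100 * sample standard deviation / mean of the replicates;
    values above 10% set the rerun flag.  The range check classifies the
    mean replicate value against the 50–3200 pg/mL window.
    """
    reps = np.asarray(measurement.replicate_values, dtype=float)
    mean = reps.mean()
    if mean == 0:
        raise ValueError(
            f"sample {measurement.sample_id!r}: all replicates zero, CV undefined"
        )
    cv = 100.0 * reps.std(ddof=1) / mean
    return QCResult(
        sample_id=measurement.sample_id,
        cv_percent=float(cv),
        rerun_flag=bool(cv > CV_RERUN_THRESHOLD),
        range_status=range_check(float(mean)),
    )


def range_check(concentration_pg_ml: float) -> RangeStatus:
    """Classify a pg/mL concentration against the assay working range.

    Bounds are inclusive; above-range samples are rerun at dilution.
    """
    if concentration_pg_ml < 0:
        raise ValueError("concentration must be nonnegative")
    lo, hi = ASSAY_RANGE_PG_ML
    if concentration_pg_ml < lo:
        return RangeStatus.BELOW_RANGE
    if concentration_pg_ml > hi:
        return RangeStatus.ABOVE_RANGE
    return RangeStatus.IN_RANGE


def recovery_efficiency(measured, expected) -> tuple[float, float]:
    """Spike-recovery efficiency: mean percent recovery and its CV.

    ``recovery_i = 100 * measured_i / expected_i``; returns
    ``(mean of recoveries, 100 * sd / mean of recoveries)``.  The CV is
    0 for a single spike.
    """
    measured = np.asarray(measured, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if measured.shape != expected.shape:
        raise ValueError("measured and expected must have equal length")
    if measured.size < 1:
        raise ValueError("need at least one spike")
    if np.any(expected <= 0):
        raise ValueError("expected values must be positive")
    rec = 100.0 * measured / expected
    mean = rec.mean()
    cv = 0.0 if rec.size == 1 else 100.0 * rec.std(ddof=1) / mean
    return float(mean), float(cv)


def bayes_linear_regression(
    x: np.ndarray,
    y: np.ndarray,
    config: ChainConfig,
) -> PosteriorSamples:
    """Bayesian simple linear regression with vague priors.

    ``y ~ Normal(intercept + slope * x, sigma)`` with priors
    ``intercept, slope ~ N(0, 10^2)`` and ``sigma ~ Half-Normal(5)``
    (sampled as log sigma).  Returns draws of intercept, slope and
    log_sigma.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sx = x.std()

    def log_post(theta: np.ndarray) -> float:
        a, b, ls = theta
        if ls < -30.0:  # numerical floor: sigma below any data scale
            return -np.inf
        sigma = np.exp(ls)
        resid = y - a - b * x
        loglik = -n * ls - 0.5 * np.sum(resid**2) / sigma**2
        logprior = -(a**2 + b**2) / 200.0 - sigma**2 / 50.0 + ls
        return loglik + logprior

    # least-squares start
    b0, a0 = np.polyfit(x, y, 1)
    resid0 = y - a0 - b0 * x
    s0 = max(float(resid0.std()), 1e-6)
    init = np.array([a0, b0, np.log(s0)])
    jitter = np.random.default_rng(config.seed).normal(
        0, 0.01, size=(config.n_chains, 3)
    )
    scales = np.array([max(s0, 1e-3), max(s0 / max(sx, 1e-6), 1e-3), 0.3])
    return sample_posterior(
        log_post,
        init + jitter,
        config,
        param_names=["intercept", "slope", "log_sigma"],
        initial_scales=scales,
    )


def _br2_draws(samples: PosteriorSamples, x: np.ndarray) -> np.ndarray:
    a = samples.flat("intercept")
    b = samples.flat("slope")
    sigma = np.exp(samples.flat("log_sigma"))
    var_fit = np.var(x) * b**2
    return var_fit / (var_fit + sigma**2)


def accuracy_test(
    added,
    measured,
    config: ChainConfig = TEST_SCALE,
) -> ValidationResult:
    """Accuracy (spike-recovery regression) validation.

    Fits a Bayesian linear regression of measured hormone on added
    standard mass and reports the posterior median slope with its 95%
    credible interval, plus the Bayesian R-squared.  A slope well above
    (below) 1 indicates over- (under-)estimation of the hormone.
    """
    added = np.asarray(added, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if added.size < 3:
        raise ValueError("need at least 3 points for the accuracy regression")
    if np.ptp(added) == 0:
        raise ValueError("added values are all equal; slope is unidentifiable")
    samples = bayes_linear_regression(added, measured, config)
    slope = samples.flat("slope")
    s_lo, s_med, s_hi = np.percentile(slope, [2.5, 50, 97.5])
    br2 = _br2_draws(samples, added)
    b_lo, b_hi = np.percentile(br2, [2.5, 97.5])
    if s_lo > 1:
        verdict = "slope above 1: hormone over-estimated"
    elif s_hi < 1:
        verdict = "slope below 1: hormone under-estimated"
    else:
        verdict = "slope consistent with 1: accurate"
    return ValidationResult(
        slope=float(s_med),
        slope_ci95=(float(s_lo), float(s_hi)),
        intercept=float(np.median(samples.flat("intercept"))),
        br2=float(br2.mean()),
        br2_ci95=(float(b_lo), float(b_hi)),
        interpretation=verdict,
    )


def parallelism_test(
    standard_curve,
    dilution_series,
    config: ChainConfig = TEST_SCALE,
) -> ParallelismResult:
    """Parallelism of a pooled serial-dilution response with the
    standard curve.

    Both curves are fitted as straight lines in response versus
    log-concentration space; the assay is parallel when the 95% credible
    interval of the slope difference (dilution minus standard) contains
    zero.
    """
    std = np.asarray(standard_curve, dtype=float)
    dil = np.asarray(dilution_series, dtype=float)
    for name, arr in (("standard_curve", std), ("dilution_series", dil)):
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
            raise ValueError(f"{name} needs at least 3 (log-dose, response) pairs")
    fit_std = bayes_linear_regression(std[:, 0], std[:, 1], config)
    cfg2 = ChainConfig(config.n_chains, config.n_iterations,
                       config.burn_in_fraction, config.thin, config.seed + 1)
    fit_dil = bayes_linear_regression(dil[:, 0], dil[:, 1], cfg2)
    diff = fit_dil.flat("slope") - fit_std.flat("slope")
    lo, hi = np.percentile(diff, [2.5, 97.5])
    return ParallelismResult(
        parallel=bool(lo <= 0 <= hi),
        slope_difference=float(np.median(diff)),
        slope_difference_ci95=(float(lo), float(hi)),
        slope_standard=float(np.median(fit_std.flat("slope"))),
        slope_dilution=float(np.median(fit_dil.flat("slope"))),
    )
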