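"""Seeded generators for synthetic whale-hormone datasets.

The generators invert the analysis models, producing data with the
statistical structure those models assume:

* female progesterone as a two-component log-normal mixture (bimodal on
  the log scale, geometric cluster centers near 1.56 and 27.12 ng/g);
* male testosterone as a log-normal series whose log-mean follows a
  365-day cosine peaking in late summer (day ~227, mid August);
* assay validation series — linear spike-recovery (reference slope
  0.83) and parallel standard/serial-dilution response curves.

Every generator is a pure function of its parameter object (which
includes the seed): identical parameters give byte-identical output.
Defaults mirror the field study being emulated: 38 female progesterone
samples (34 females, four resampled) and 45 male testosterone samples
(44 males, one resampled), collected between late winter and early
autumn.  Within-cluster log-scale spreads (0.55, 0.85) and the seasonal
amplitude (1.0 log-unit) are plausibility choices: the reference
analysis reports only posterior summaries of the cluster centers, not
within-cluster spreads or the amplitude itself.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from .data import Dataset, Hormone, HormoneRecord, Sex

__all__ = [
    "MixtureSimParams",
    "SeasonalSimParams",
    "AssaySimParams",
    "AssaySeries",
    "gen_mixture_concentrations",
    "gen_seasonal_concentrations",
    "gen_assay_series",
]

# non-leap reference year used to materialise day-of-year as a date
_BASE_YEAR = 2015


def _date_from_doy(doy: int) -> _dt.date:
    return _dt.date(_BASE_YEAR, 1, 1) + _dt.timedelta(days=int(doy) - 1)


@dataclass(frozen=True)
class MixtureSimParams:
    """Two-component log-normal mixture for female progesterone.

    ``weight_A`` is the probability a female belongs to the low cluster
    (cluster A); geometric means are in ng/g and log-sds on the natural
    log scale.  Labelling is canonical: cluster A is the lower one.
    """

    n: int = 38
    weight_A: float = 0.61
    geo_mean_A: float = 1.56
    geo_mean_B: float = 27.12
    log_sd_A: float = 0.55
    log_sd_B: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 < self.weight_A < 1:
            raise ValueError("weight_A must lie strictly in (0, 1)")
        if not (self.geo_mean_A > 0 and self.geo_mean_B > 0):
            raise ValueError("geometric means must be positive")
        if self.geo_mean_A >= self.geo_mean_B:
            raise ValueError("canonical labelling requires geo_mean_A < geo_mean_B")
        if not (self.log_sd_A > 0 and self.log_sd_B > 0):
            raise ValueError("log-scale sds must be positive (degenerate "
                             "zero-spread clusters are rejected)")


@dataclass(frozen=True)
class SeasonalSimParams:
    """Log-normal testosterone with a 365-day cosine seasonal log-mean.

    ``log y = alpha + amplitude * cos(2*pi*(day - peak_day)/365) + noise``
    with days drawn uniformly (integers) from ``day_range``.  The default
    window [30, 300] reproduces the sampling-effort gap of the field
    study (no autumn/early-winter biopsies).
    """

    n: int = 45
    alpha: float = np.log(0.88)
    amplitude: float = 1.0
    peak_day: float = 227.0
    sigma: float = 0.7
    day_range: tuple[int, int] = (30, 300)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if not 1 <= self.peak_day <= 365:
            raise ValueError("peak_day must lie in [1, 365]")
        lo, hi = self.day_range
        if not (1 <= lo <= hi <= 365):
            raise ValueError("day_range must be a nonempty interval within [1, 365]")


@dataclass(frozen=True)
class AssaySimParams:
    """Spike-recovery (accuracy) and parallelism series parameters.

    The accuracy series is ``measured = intercept + true_slope * added
    + noise``; the default slope 0.83 is the reference assay's
    progesterone value.  The parallelism pair is a standard curve and a
    pooled-sample serial-dilution response, linear in log-concentration,
    whose slopes differ by the factor ``dilution_slope_ratio`` (1.0
    means truly parallel).
    """

    true_slope: float = 0.83
    intercept: float = 0.0
    noise_sd: float = 0.02
    added_masses: tuple[float, ...] = (0.05, 0.1, 0.2, 0.4, 0.8, 1.6, 3.2)
    dilution_steps: int = 6
    dilution_slope_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if any(b <= a for a, b in zip(self.added_masses, self.added_masses[1:])):
            raise ValueError("added_masses must be strictly increasing")
        if self.dilution_steps < 3:
            raise ValueError("need at least 3 dilution steps")


@dataclass(frozen=True)
class AssaySeries:
    """Output of :func:`gen_assay_series`.

    ``added``/``measured`` are the accuracy (spike-recovery) series;
    ``standard_curve`` and ``dilution_series`` are (log-concentration,
    response) pairs for the parallelism test.
    """

    added: np.ndarray
    measured: np.ndarray
    standard_curve: np.ndarray  # shape (k, 2): log-dose, response
    dilution_series: np.ndarray  # shape (m, 2): log-dilution, response


def gen_mixture_concentrations(
    params: MixtureSimParams,
) -> tuple[Dataset, np.ndarray]:
    """Simulate female progesterone records from the two-cluster model.

    Returns the dataset and the true cluster labels (0 = cluster A,
    1 = cluster B), which parameter-recovery tests compare against.
    """
    rng = np.random.default_rng(params.seed)
    in_b = rng.random(params.n) < (1.0 - params.weight_A)
    mu = np.where(in_b, np.log(params.geo_mean_B), np.log(params.geo_mean_A))
    sd = np.where(in_b, params.log_sd_B, params.log_sd_A)
    conc = np.exp(rng.normal(mu, sd))
    days = rng.integers(30, 301, size=params.n)
    records = [
        HormoneRecord(
            whale_id=f"F{i + 1:03d}",
            sex=Sex.FEMALE,
            hormone=Hormone.PROGESTERONE,
            concentration=float(conc[i]),
            date=_date_from_doy(days[i]),
        )
        for i in range(params.n)
    ]
    ds = Dataset(records, provenance=f"synthetic mixture seed={params.seed}")
    return ds, in_b.astype(int)


def gen_seasonal_concentrations(params: SeasonalSimParams) -> Dataset:
    """Simulate male testosterone records from the seasonal cosine model."""
    rng = np.random.default_rng(params.seed)
    lo, hi = params.day_range
    days = rng.integers(lo, hi + 1, size=params.n)
    mean_log = params.alpha + params.amplitude * np.cos(
        2 * np.pi * (days - params.peak_day) / 365.0
    )
    conc = np.exp(mean_log + rng.normal(0.0, params.sigma, size=params.n))
    records = [
        HormoneRecord(
            whale_id=f"M{i + 1:03d}",
            sex=Sex.MALE,
            hormone=Hormone.TESTOSTERONE,
            concentration=float(conc[i]),
            date=_date_from_doy(days[i]),
        )
        for i in range(params.n)
    ]
    return Dataset(records, provenance=f"synthetic seasonal seed={params.seed}")


def gen_assay_series(params: AssaySimParams) -> AssaySeries:
    """Simulate assay validation series.

    Accuracy: one measured value per added mass with Gaussian noise.
    Parallelism: the standard curve is a noiseless line in
    response-vs-log-concentration space (slope -1, intercept 1 —
    competitive-assay-like, falling response with dose); the pooled
    serial-dilution response shares that slope scaled by
    ``dilution_slope_ratio``, plus measurement noise.
    """
    rng = np.random.default_rng(params.seed)
    added = np.asarray(params.added_masses, dtype=float)
    measured = (
        params.intercept
        + params.true_slope * added
        + rng.normal(0.0, params.noise_sd, size=added.size)
    )

    std_slope, std_intercept = -1.0, 1.0
    log_dose = np.log2(added / added[0])
    standard = np.column_stack([log_dose, std_intercept + std_slope * log_dose])

    log_dil = -np.arange(params.dilution_steps, dtype=float)  # 1, 1/2, 1/4, ...
    dil_resp = (
        std_intercept
        + std_slope * params.dilution_slope_ratio * log_dil
        + rng.normal(0.0, params.noise_sd, size=log_dil.size)
    )
    dilution = np.column_stack([log_dil, dil_resp])
    return AssaySeries(added=added, measured=measured,
                       standard_curve=standard, dilution_series=dilution)
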