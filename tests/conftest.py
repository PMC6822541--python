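import warnings

import numpy as np
import pytest

from finhorm import ChainConfig
from finhorm.mixture import fit_mixture
from finhorm.seasonal import augment_winter_replication, fit_seasonal
from finhorm.synthetic import (
    MixtureSimParams,
    SeasonalSimParams,
    gen_mixture_concentrations,
    gen_seasonal_concentrations,
)

warnings.filterwarnings("ignore", message=".*ArviZ.*")

#: light chain layout for unit tests (posterior shapes, not precision)
FAST = ChainConfig(n_chains=3, n_iterations=4000, burn_in_fraction=0.1,
                   thin=2, seed=0)


def fast(seed=0, n_chains=3, n_iterations=4000, thin=2):
    return ChainConfig(n_chains, n_iterations, 0.1, thin, seed)


@pytest.fixture(scope="session")
def mixture_recovery_fit():
    """One moderately sized mixture fit shared across tests: n=300 at
    the reference cluster geometry (geo-means 1.56/27.12, weight_A
    0.61), seed 3."""
    ds, labels = gen_mixture_concentrations(MixtureSimParams(n=300, seed=3))
    fit = fit_mixture(ds.concentrations,
                      ChainConfig(3, 12000, 0.1, 4, seed=3))
    return ds, labels, fit


@pytest.fixture(scope="session")
def seasonal_recovery_fit():
    """Strong-signal seasonal fit shared across tests: n=84, amplitude
    1.0 log-units, peak day 227, sigma 0.7, winter-replicated."""
    ds = gen_seasonal_concentrations(
        SeasonalSimParams(n=84, amplitude=1.0, peak_day=227.0, sigma=0.7,
                          seed=11))
    aug = augment_winter_replication(ds)
    fit = fit_seasonal(aug, ChainConfig(3, 12000, 0.1, 4, seed=7))
    return ds, aug, fit
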