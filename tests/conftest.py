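import numpy as np
import pytest
from hypothesis import settings
from scipy import stats

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from aerodep.impactor_reduction import ImpactorRun, StageDeposit


def lognormal_run(amad, gsd, n_stages=96, span_sigmas=4.5, total=1e6):
    """Noiseless impactor run sampled from lognormal(amad, gsd) on a dense
    ladder covering +/- span_sigmas ln-GSD around the median.

    Built directly from the closed-form lognormal CDF, independent of the
    synthetic_data generator, so it can serve as its oracle too.
    """
    sigma = np.log(gsd)
    bounds = np.exp(
        np.linspace(
            np.log(amad) - span_sigmas * sigma,
            np.log(amad) + span_sigmas * sigma,
            n_stages + 1,
        )
    )
    cdf = stats.norm.cdf((np.log(bounds) - np.log(amad)) / sigma)
    mass = np.diff(cdf)
    mass[0] += cdf[0]
    mass[-1] += 1 - cdf[-1]
    stages = [
        StageDeposit(i + 1, bounds[i], bounds[i + 1], total * mass[i])
        for i in range(n_stages)
    ]
    return ImpactorRun(stages)


@pytest.fixture
def dense_run():
    return lognormal_run


@pytest.fixture
def two_stage_run():
    return ImpactorRun(
        [StageDeposit(1, 0.1, 1.0, 30.0), StageDeposit(2, 1.0, 10.0, 70.0)]
    )

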