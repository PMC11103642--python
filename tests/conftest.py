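import datetime as dt

import numpy as np
import pytest

import owlsurv as o
from owlsurv.cjs import EncounterData
from owlsurv.snow import SnowScaling


@pytest.fixture(scope="session")
def study_cal():
    return o.study_calendar()


@pytest.fixture()
def flat_calendar():
    """Ten all-summer, all-full-effort occasions: the simplest CJS setting."""
    return o.build_occasion_calendar(dt.date(2009, 5, 15), 6)


def make_constant_params(phi, p, n=0):
    """Parameter point with season-independent survival and detection."""
    pv = o.ParameterVector.from_seasonal_survival(
        {s: phi for s in o.SEASONS}, p_full=p, p_reduced=p
    )
    if n:
        pv.eps = np.zeros(n)
    return pv


@pytest.fixture()
def tiny_dataset():
    """A 40-bird, 12-occasion dataset for fast inference smoke tests."""
    cal = o.build_occasion_calendar(dt.date(2009, 5, 15), 12)
    rng = np.random.default_rng(5)
    tags = [dt.date(2009, 5, 20) for _ in range(40)]
    ind = o.IndividualTable(
        individual=np.arange(1, 41),
        brood=np.arange(1, 41),
        sex=rng.integers(0, 2, 40),
        mass_z=rng.normal(size=40),
        fed=rng.integers(0, 2, 40),
        release_occ=np.zeros(40, dtype=np.int64),
        tagging_date=tags,
    )
    params = make_constant_params(0.9, 0.9, n=40)
    data, truth = o.simulate_encounters(ind, params, cal, SnowScaling(0.0, 1.0), seed=11)
    return data, truth


# ---------------------------------------------------------------------------
# Study-scale recovery fits: expensive, shared across the acceptance tests for
# interval coverage, snow-effect evidence, and predictive-check calibration.
# ---------------------------------------------------------------------------

N_RECOVERY_FITS = 20
RECOVERY_MCMC = o.MCMCSettings(n_chains=2, n_iter=1400, burn_in=500, thin=2)


@pytest.fixture(scope="session")
def recovery_fits():
    """Fit the model to study-scale synthetic datasets generated at the
    default (study-median) truth; return (truth, samples, ppc) triples."""
    out = []
    for seed in range(1, N_RECOVERY_FITS + 1):
        data, truth, _ = o.simulate_study_dataset(seed=seed)
        samples = o.sample_posterior(data, mcmc=RECOVERY_MCMC, seed=1000 + seed)
        ppc = o.posterior_predictive_pvalue(samples, data, seed=seed, max_draws=300)
        out.append((truth, samples, ppc))
    return out
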