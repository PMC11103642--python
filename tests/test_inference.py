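import datetime as dt

import numpy as np
import pytest
from scipy.special import expit, logit

import owlsurv as o
from owlsurv.cjs import EncounterData, ParameterVector, detection_prob_matrix, survival_logit_matrix
from owlsurv.inference import (
    SCALAR_PARAMS,
    PosteriorSamples,
    _simulate_replicate,
    expected_m_array,
    freeman_tukey,
    m_array,
    pool_m_array,
)
from owlsurv.occasions import SEASONS
from owlsurv.snow import SnowScaling

from conftest import make_constant_params


def _params(**kw):
    base = dict(alpha_season=logit(np.full(4, 0.9)), p_full=0.9, p_reduced=0.6, sigma_det=0.5)
    base.update(kw)
    return ParameterVector(**base)


class TestLogPrior:
    def test_support_violations(self):
        assert o.log_prior(_params(p_full=0.65)) == -np.inf
        assert o.log_prior(_params(p_reduced=0.95)) == -np.inf
        assert np.isfinite(o.log_prior(_params()))

    def test_survival_prior_peaks_at_beta_mode(self):
        """Beta(95,10) has mode 94/103 and mean 95/105; the prior density of
        the baseline survival should peak at the mode."""
        mode = 94 / 103
        lp_mode = o.log_prior(_params(alpha_season=logit(np.full(4, mode))))
        for s in (0.85, 0.88, 0.93, 0.95):
            assert lp_mode > o.log_prior(_params(alpha_season=logit(np.full(4, s))))
        assert 95 / 105 == pytest.approx(0.9048, abs=5e-5)

    def test_eps_hierarchical_term(self):
        pv = _params()
        pv.eps = np.zeros(10)
        base = o.log_prior(pv)
        pv2 = _params()
        pv2.eps = np.full(10, 2.0)
        assert o.log_prior(pv2) < base


class TestSamplePosterior:
    def test_deterministic_given_seed(self, tiny_dataset):
        data, _ = tiny_dataset
        mcmc = o.MCMCSettings(n_chains=2, n_iter=60, burn_in=20, thin=2)
        s1 = o.sample_posterior(data, mcmc=mcmc, seed=42)
        s2 = o.sample_posterior(data, mcmc=mcmc, seed=42)
        for k in SCALAR_PARAMS:
            assert np.array_equal(s1.draws[k], s2.draws[k])

    def test_thinning_contract(self, tiny_dataset):
        data, _ = tiny_dataset
        mcmc = o.MCMCSettings(n_chains=3, n_iter=130, burn_in=10, thin=6)
        s = o.sample_posterior(data, mcmc=mcmc, seed=1)
        assert s.n_chains == 3
        assert s.n_draws == (130 - 10) // 6

    def test_draws_respect_prior_supports(self, tiny_dataset):
        data, _ = tiny_dataset
        mcmc = o.MCMCSettings(n_chains=2, n_iter=150, burn_in=30, thin=2)
        s = o.sample_posterior(data, mcmc=mcmc, seed=3)
        assert (s.flat("p_full") > 0.7).all() and (s.flat("p_full") < 1.0).all()
        assert (s.flat("p_reduced") > 0.3).all() and (s.flat("p_reduced") < 0.9).all()
        assert (s.flat("sigma_det") > 0).all()

    def test_recovers_survival_on_perfect_detection(self):
        """With p = 1 and constant survival 0.9, the posterior for summer
        biweekly survival concentrates near the truth."""
        cal = o.build_occasion_calendar(dt.date(2009, 5, 15), 7)
        n = 300
        from test_simulate import _uniform_individuals

        ind = _uniform_individuals(cal, n=n, release=0)
        pv = make_constant_params(0.9, 1 - 1e-9, n=n)
        pv.sigma_det = 0.0
        data, truth = o.simulate_encounters(ind, pv, cal, SnowScaling(0, 1), seed=2)
        mcmc = o.MCMCSettings(n_chains=2, n_iter=600, burn_in=200, thin=2)
        s = o.sample_posterior(data, mcmc=mcmc, seed=5)
        med = float(np.median(expit(s.flat("alpha_summer"))))
        assert abs(med - 0.9) < 0.03


class TestFastLikelihoodPath:
    def test_matches_reference_when_no_bird_released_at_first_occasion(self):
        """The sampler's scaled forward pass must agree with the reference
        log-space likelihood even when the earliest release is late."""
        import datetime as dt

        from owlsurv.inference import _Model
        from owlsurv.cjs import SeasonMask
        from owlsurv.cjs import cjs_loglik_matrix
        import owlsurv as o
        from test_simulate import _uniform_individuals

        cal = o.build_occasion_calendar(dt.date(2009, 5, 15), 10)
        ind = _uniform_individuals(cal, n=60, release=2)  # June tagging
        pv = make_constant_params(0.9, 0.8, n=60)
        pv.sigma_det = 0.4
        data, truth = o.simulate_encounters(ind, pv, cal, SnowScaling(0, 1), seed=6)
        assert data.f.min() > 0  # no bird released in occasion 1
        pv = truth.params
        m = _Model(data, SeasonMask())
        betas = np.array([pv.beta_snow_surv, pv.beta_mass, pv.beta_sex, pv.beta_fed])
        phi = m.phi(pv.alpha_season, betas)
        p = m.p(np.array([pv.p_full, pv.p_reduced]), pv.beta_snow_det, pv.eps)
        ref = cjs_loglik_matrix(data.y, data.f, phi, p)
        assert np.allclose(m.loglik_vector(phi, p), ref, atol=1e-10)
        # the JIT kernel and the numpy fallback perform the same computation
        assert np.allclose(m.loglik_vector(phi, p), m._loglik_vector_np(phi, p), atol=1e-12)


class TestGelmanRubin:
    def _samples(self, arrays):
        draws = {k: arrays for k in SCALAR_PARAMS}
        return PosteriorSamples(draws=dict(draws), meta={})

    def test_identical_chains_converged(self):
        rng = np.random.default_rng(0)
        one = rng.normal(size=(1, 500))
        s = self._samples(np.vstack([one, one]).reshape(2, 500))
        out = o.gelman_rubin(s)
        assert all(v < 1.02 for v in out["rhat"].values())

    def test_same_distribution_passes(self):
        rng = np.random.default_rng(1)
        s = self._samples(rng.normal(size=(3, 1000)))
        out = o.gelman_rubin(s)
        assert out["converged"]
        assert all(v < 1.02 for v in out["rhat"].values())

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(2, 1000))
        chains[1] += 5.0
        out = o.gelman_rubin(self._samples(chains))
        assert not out["converged"]
        assert all(v > 1.5 for v in out["rhat"].values())

    def test_single_chain_raises(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            o.gelman_rubin(self._samples(rng.normal(size=(1, 100))))


class TestMArray:
    def test_small_example_by_hand(self):
        # three birds, four occasions
        y = np.array([[1, 1, 0, 1], [0, 1, 0, 0], [1, 0, 0, 1]])
        f = np.array([0, 1, 0])
        m = m_array(y, f)
        assert m.shape == (3, 4)
        assert m[0, 0] == 1  # bird 1: 0 -> 1
        assert m[1, 2] == 1  # bird 1: 1 -> 3
        assert m[0, 2] == 1  # bird 3: 0 -> 3
        assert m[1, 3] == 1  # bird 2 released at 1, never seen again
        assert m.sum() == 4

    def test_expected_matches_simulation_mean(self):
        """The analytic expected m-array equals the Monte-Carlo mean of
        simulated replicate m-arrays (the independent check of the PPC's
        expectation formula)."""
        rng = np.random.default_rng(7)
        n, T = 40, 6
        f = np.repeat([0, 1], [25, 15])
        phi = np.clip(rng.uniform(0.7, 0.95, (n, T)), 0, 1)
        p = np.clip(rng.uniform(0.4, 0.9, (n, T)), 0, 1)
        reps = 3000
        acc = np.zeros((T - 1, T))
        exp_acc = np.zeros((T - 1, T))
        for _ in range(reps):
            y = _simulate_replicate(rng, f, phi, p)
            acc += m_array(y, f)
            exp_acc += expected_m_array(phi, p, y, f)
        # mean observed cell counts vs mean conditional expectations
        assert np.abs(acc / reps - exp_acc / reps).max() < 0.15

    def test_pooling_preserves_total(self):
        rng = np.random.default_rng(9)
        data, truth, _ = o.simulate_study_dataset(seed=31, n_per_cohort=20)
        m = m_array(data.y, data.f)
        pooled = pool_m_array(m, data.calendar.seasons())
        assert pooled.sum() == m.sum()
        assert pooled.shape[1] == 4

    def test_freeman_tukey_zero_on_identical(self):
        x = np.array([[4.0, 1.0], [0.0, 2.0]])
        assert freeman_tukey(x, x) == 0.0


class TestPosteriorPredictive:
    def test_requires_enough_draws(self, tiny_dataset):
        data, _ = tiny_dataset
        mcmc = o.MCMCSettings(n_chains=2, n_iter=50, burn_in=10, thin=2)
        s = o.sample_posterior(data, mcmc=mcmc, seed=0)
        with pytest.raises(ValueError, match="100"):
            o.posterior_predictive_pvalue(s, data)

    def test_pvalue_in_unit_interval_and_deterministic(self, tiny_dataset):
        data, _ = tiny_dataset
        mcmc = o.MCMCSettings(n_chains=2, n_iter=140, burn_in=20, thin=2)
        s = o.sample_posterior(data, mcmc=mcmc, seed=0)
        out1 = o.posterior_predictive_pvalue(s, data, seed=5, max_draws=40)
        out2 = o.posterior_predictive_pvalue(s, data, seed=5, max_draws=40)
        assert 0.0 <= out1["bayesian_p"] <= 1.0
        assert out1 == out2

    def test_replicates_respect_structural_zeros(self):
        data, truth, _ = o.simulate_study_dataset(seed=13, n_per_cohort=20)
        pv = truth.params
        phi = expit(survival_logit_matrix(pv, data))
        p = detection_prob_matrix(pv, data)
        rng = np.random.default_rng(0)
        y_rep = _simulate_replicate(rng, data.f, phi, p)
        assert y_rep[:, data.calendar.effort() == "none"].sum() == 0
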