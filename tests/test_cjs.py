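import datetime as dt
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logit

import owlsurv as o
from owlsurv.cjs import (
    EncounterData,
    ParameterVector,
    SeasonMask,
    brute_force_loglik,
    cjs_loglik_individual,
    cjs_loglik_matrix,
    cjs_loglik_total,
    detection_prob,
    detection_prob_matrix,
    survival_logit,
    survival_logit_matrix,
)
from owlsurv.snow import SnowScaling

from conftest import make_constant_params


def random_case(rng, L):
    """Random history (release at 0) with admissible phi/p vectors."""
    h = np.concatenate([[1], rng.integers(0, 2, L - 1)])
    phi = rng.uniform(0.05, 0.99, L - 1)
    p = rng.uniform(0.05, 0.99, L)
    return h, phi, p


class TestPredictors:
    def setup_method(self):
        self.pv = ParameterVector(
            alpha_season=np.array([1.0, 2.0, 3.0, 2.5]),
            beta_snow_surv=-0.4,
            beta_mass=0.5,
            beta_sex=0.15,
            beta_fed=0.3,
        )

    def test_intercept_identity(self):
        eta = survival_logit(self.pv, mass_z=0, sex=0, fed=0, season="winter", snow_x=0)
        assert eta == pytest.approx(3.0)

    def test_snow_linearity(self):
        e1 = survival_logit(self.pv, 0, 0, 0, "winter", snow_x=0.3)
        e2 = survival_logit(self.pv, 0, 0, 0, "winter", snow_x=1.3)
        assert e2 - e1 == pytest.approx(self.pv.beta_snow_surv)

    def test_season_mask_contract(self):
        """With the default summer-only masks, winter survival is numerically
        independent of mass and feeding."""
        a = survival_logit(self.pv, mass_z=2.5, sex=0, fed=1, season="winter", snow_x=0)
        b = survival_logit(self.pv, mass_z=-1.0, sex=0, fed=0, season="winter", snow_x=0)
        assert a == b
        a = survival_logit(self.pv, 2.5, 0, 1, "summer", 0)
        b = survival_logit(self.pv, -1.0, 0, 0, "summer", 0)
        assert a - b == pytest.approx(3.5 * 0.5 + 0.3)

    def test_unknown_season_raises(self):
        with pytest.raises(ValueError):
            survival_logit(self.pv, 0, 0, 0, "monsoon", 0)

    def test_detection_structural_zero(self):
        pv = ParameterVector(alpha_season=np.zeros(4), p_full=0.99, p_reduced=0.5)
        assert detection_prob(pv, "none", snow_x=5.0, eps_i=10.0) == 0.0

    def test_detection_baseline_and_snow_shift(self):
        pv = ParameterVector(
            alpha_season=np.zeros(4), p_full=0.95, p_reduced=0.6, beta_snow_det=-0.229
        )
        assert detection_prob(pv, "full", 0.0) == pytest.approx(0.95)
        assert detection_prob(pv, "reduced", 0.0) == pytest.approx(0.6)
        p0 = detection_prob(pv, "full", 1.0)
        p1 = detection_prob(pv, "full", 2.0)
        assert logit(p0) - logit(p1) == pytest.approx(0.229)


class TestIndividualLikelihood:
    def test_closed_forms(self):
        assert cjs_loglik_individual([1, 1], [0.8], [0.5, 0.6]) == pytest.approx(
            np.log(0.8 * 0.6)
        )
        assert cjs_loglik_individual([1, 0], [0.8], [0.5, 0.6]) == pytest.approx(
            np.log(0.2 + 0.8 * 0.4)
        )

    def test_certain_survival_and_detection(self):
        h = np.ones(7, dtype=int)
        assert cjs_loglik_individual(h, np.ones(6), np.ones(7)) == pytest.approx(0.0)
        assert brute_force_loglik(h, np.ones(6), np.ones(7)) == pytest.approx(0.0)

    def test_impossible_datum_raises(self):
        with pytest.raises(ValueError, match="p = 0"):
            cjs_loglik_individual([1, 1], [0.9], [0.5, 0.0])
        with pytest.raises(ValueError, match="p = 0"):
            brute_force_loglik([1, 1], [0.9], [0.5, 0.0])

    def test_exhaustive_oracle_equivalence_short_histories(self):
        """Forward recursion equals death-time enumeration on every binary
        history of up to 6 occasions (longer exhaustive sweep lives in the
        acceptance suite)."""
        rng = np.random.default_rng(2)
        for L in range(1, 7):
            phi = rng.uniform(0.05, 0.99, L - 1)
            p = rng.uniform(0.05, 0.99, L)
            for tail in itertools.product([0, 1], repeat=L - 1):
                h = np.array((1,) + tail)
                assert cjs_loglik_individual(h, phi, p) == pytest.approx(
                    brute_force_loglik(h, phi, p), abs=1e-12
                )

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 10_000), st.integers(2, 14))
    def test_oracle_equivalence_random(self, seed, L):
        rng = np.random.default_rng(seed)
        h, phi, p = random_case(rng, L)
        assert cjs_loglik_individual(h, phi, p) == pytest.approx(
            brute_force_loglik(h, phi, p), abs=1e-12
        )

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 10_000), st.integers(2, 10))
    def test_loglik_nonpositive_and_monotone_in_phi(self, seed, L):
        rng = np.random.default_rng(seed)
        h, phi, p = random_case(rng, L)
        ll = cjs_loglik_individual(h, phi, p)
        assert ll <= 1e-12
        # for an all-detected history, raising any phi raises the likelihood
        h1 = np.ones(L, dtype=int)
        phi2 = phi.copy()
        j = rng.integers(L - 1)
        phi2[j] = min(1.0, phi2[j] + 0.1 * (1 - phi2[j]))
        assert cjs_loglik_individual(h1, phi2, p) >= cjs_loglik_individual(h1, phi, p)


class TestTotalLikelihood:
    def test_empty_data_is_zero(self, flat_calendar):
        data = EncounterData.build(
            y=np.zeros((0, 6), dtype=int),
            f=np.zeros(0, dtype=int),
            mass_z=np.zeros(0),
            sex=np.zeros(0),
            fed=np.zeros(0),
            calendar=flat_calendar,
            snow_scaling=SnowScaling(0.0, 1.0),
        )
        assert cjs_loglik_total(data, make_constant_params(0.9, 0.8, n=0)) == 0.0

    def test_matches_scalar_path_and_is_permutation_invariant(self, tiny_dataset):
        data, truth = tiny_dataset
        pv = truth.params
        phi = expit(survival_logit_matrix(pv, data))
        p = detection_prob_matrix(pv, data)
        per_ind = cjs_loglik_matrix(data.y, data.f, phi, p)
        for i in (0, 7, 23):
            fi = data.f[i]
            ll = cjs_loglik_individual(data.y[i, fi:], phi[i, fi:-1], p[i, fi:])
            assert per_ind[i] == pytest.approx(ll, abs=1e-10)
        total = cjs_loglik_total(data, pv)
        assert total == pytest.approx(per_ind.sum())
        # permuting individuals leaves the total unchanged
        perm = np.random.default_rng(0).permutation(data.n_individuals)
        data2 = EncounterData.build(
            y=data.y[perm],
            f=data.f[perm],
            mass_z=data.mass_z[perm],
            sex=data.sex[perm],
            fed=data.fed[perm],
            calendar=data.calendar,
            snow_scaling=data.snow_scaling,
        )
        pv2 = ParameterVector(**{**pv.__dict__})
        pv2.eps = pv.eps[perm]
        assert cjs_loglik_total(data2, pv2) == pytest.approx(total)

    def test_effort_free_occasions_are_likelihood_neutral(self):
        """Inserting an effort=none occasion leaves each history's likelihood
        equal to the collapsed problem with the occasion removed and its two
        survival intervals multiplied."""
        rng = np.random.default_rng(4)
        for _ in range(50):
            L = 7
            h, phi, p = random_case(rng, L)
            # insert a none occasion after position k (p=0, y=0)
            k = int(rng.integers(1, L))
            h2 = np.insert(h, k, 0)
            p2 = np.insert(p, k, 0.0)
            # split interval k-1 -> k into two sub-intervals with product phi
            a = rng.uniform(phi[k - 1], 1.0)
            phi2 = np.insert(phi, k - 1, a)
            phi2[k] = phi[k - 1] / a
            ll_orig = cjs_loglik_individual(h, phi, p)
            ll_aug = cjs_loglik_individual(h2, phi2, p2)
            assert ll_aug == pytest.approx(ll_orig, abs=1e-10)


class TestEncounterDataContracts:
    def test_release_detection_enforced(self, flat_calendar):
        y = np.zeros((2, 6), dtype=int)
        y[0, 0] = 1  # second bird's release detection missing
        with pytest.raises(ValueError, match="release"):
            EncounterData.build(
                y=y,
                f=np.array([0, 1]),
                mass_z=np.zeros(2),
                sex=np.zeros(2),
                fed=np.zeros(2),
                calendar=flat_calendar,
                snow_scaling=SnowScaling(0.0, 1.0),
            )

    def test_csv_round_trip_with_missing_code(self, tmp_path, study_cal):
        data, truth, ind = o.simulate_study_dataset(seed=12, n_per_cohort=15)
        enc = data.encounters_frame()
        none_cols = [f"occ{t+1}" for t in np.flatnonzero(data.calendar.effort() == "none")]
        assert (enc[none_cols] == -9).all().all()
        enc.to_csv(tmp_path / "encounters.csv", index=False)
        data.individuals_frame().to_csv(tmp_path / "individuals.csv", index=False)
        import pandas as pd

        back = EncounterData.from_frames(
            pd.read_csv(tmp_path / "encounters.csv"),
            pd.read_csv(tmp_path / "individuals.csv"),
            data.calendar,
            data.snow_scaling,
        )
        assert np.array_equal(back.y, data.y)
        assert np.array_equal(back.f, data.f)
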