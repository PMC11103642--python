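"""Cormack–Jolly–Seber likelihood core.

The model follows juvenile birds from their release (first radio-tagged)
occasion.  Biweekly apparent survival φ is logit-linear in a seasonal
intercept, a standardised snow-days covariate, and individual covariates
(age-corrected body mass, sex, nestling supplementary feeding) whose effect
can be restricted to a subset of seasons via a season mask.  Detection p is
structured by field effort: structurally zero in occasions without tracking,
and otherwise an effort-regime baseline (full vs reduced) shifted on the
logit scale by the snow covariate and an individual random effect.

The likelihood is the marginal CJS likelihood: the latent alive/dead chain is
summed out exactly with a two-state forward recursion (conditioning on first
release), rather than sampled by data augmentation.  A brute-force
enumeration over death intervals is provided as an independent oracle.

Conventions: occasion indices are 0-based internally; φ[:, t] is survival
over the interval from occasion t to t+1 and is built from occasion t's
season and snow value; p[:, t] applies to detection at occasion t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .occasions import SEASONS, OccasionCalendar, season_index_matrix
from .snow import SnowScaling, snow_covariate

__all__ = [
    "SeasonMask",
    "ParameterVector",
    "EncounterData",
    "survival_logit",
    "survival_logit_matrix",
    "detection_prob",
    "detection_prob_matrix",
    "cjs_loglik_individual",
    "brute_force_loglik",
    "cjs_loglik_matrix",
    "cjs_loglik_total",
]

ALL_SEASONS = frozenset(SEASONS)
MISSING_CODE = -9  # structurally unobservable cells in encounters.csv


@dataclass(frozen=True)
class SeasonMask:
    """Seasons in which each individual covariate is allowed to act on survival.

    The default restricts the body-mass and feeding effects to the summer
    post-fledging period while sex acts year-round; setting a mask to all four
    seasons gives the alternative formulation in which early-life covariates
    affect survival throughout the first year.
    """

    mass: frozenset = frozenset({"summer"})
    fed: frozenset = frozenset({"summer"})
    sex: frozenset = ALL_SEASONS

    def __post_init__(self) -> None:
        for name in ("mass", "fed", "sex"):
            object.__setattr__(self, name, frozenset(getattr(self, name)))
            if not getattr(self, name) <= ALL_SEASONS:
                raise ValueError(f"mask {name} contains unknown seasons")

    def indicator(self, name: str) -> np.ndarray:
        """0/1 vector over the canonical season order."""
        active = getattr(self, name)
        return np.array([1.0 if s in active else 0.0 for s in SEASONS])

    @classmethod
    def all_seasons(cls) -> "SeasonMask":
        return cls(mass=ALL_SEASONS, fed=ALL_SEASONS, sex=ALL_SEASONS)


@dataclass
class ParameterVector:
    """One point in parameter space.

    ``alpha_season`` are logit-scale survival intercepts in canonical season
    order (summer, autumn, winter, spring) — i.e. the biweekly survival of an
    average-mass, unfed female at snow covariate 0.  Detection baselines
    ``p_full``/``p_reduced`` live on the probability scale (their priors are
    uniform on bounded probability intervals); snow and the individual random
    effects ``eps`` shift detection additively on the logit scale.
    """

    alpha_season: np.ndarray  # shape (4,), logit scale
    beta_snow_surv: float = 0.0
    beta_mass: float = 0.0
    beta_sex: float = 0.0
    beta_fed: float = 0.0
    p_full: float = 0.95
    p_reduced: float = 0.6
    beta_snow_det: float = 0.0
    sigma_det: float = 0.0
    eps: np.ndarray | None = None  # per-individual detection random effects

    def __post_init__(self) -> None:
        self.alpha_season = np.asarray(self.alpha_season, dtype=float)
        if self.alpha_season.shape != (4,):
            raise ValueError("alpha_season must have one intercept per season")
        if not (0.0 < self.p_full < 1.0 and 0.0 < self.p_reduced < 1.0):
            raise ValueError("detection baselines must be probabilities in (0,1)")
        if self.sigma_det < 0:
            raise ValueError("sigma_det must be non-negative")
        if self.eps is not None:
            self.eps = np.asarray(self.eps, dtype=float)

    @classmethod
    def from_seasonal_survival(cls, phi_by_season: dict[str, float], **kw) -> "ParameterVector":
        """Build from biweekly survival probabilities keyed by season name."""
        alpha = np.array([logit(phi_by_season[s]) for s in SEASONS])
        return cls(alpha_season=alpha, **kw)

    def baseline_survival(self) -> dict[str, float]:
        return {s: float(expit(a)) for s, a in zip(SEASONS, self.alpha_season)}


@dataclass
class EncounterData:
    """Encounter histories plus everything the predictors need.

    ``y`` is the n×T binary detection matrix, ``f`` the 0-based release
    occasion per individual (``y[i, f[i]] == 1`` by construction), and
    ``season_idx`` the per-individual season index matrix implementing the
    cohort-year resolution of the spring/summer overlap.  ``snow_x`` is the
    per-occasion standardised snow covariate (0 outside winter).
    """

    y: np.ndarray
    f: np.ndarray
    mass_z: np.ndarray
    sex: np.ndarray
    fed: np.ndarray
    calendar: OccasionCalendar
    snow_x: np.ndarray
    snow_scaling: SnowScaling
    season_idx: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int8)
        self.f = np.asarray(self.f, dtype=np.int64)
        n, T = self.y.shape
        if T != len(self.calendar):
            raise ValueError("encounter matrix and calendar disagree on T")
        if self.season_idx.shape != (n, T):
            raise ValueError("season_idx must be n x T")
        if not (self.y[np.arange(n), self.f] == 1).all():
            raise ValueError("every individual must be detected at its release occasion")
        none_occ = self.calendar.effort() == "none"
        if self.y[:, none_occ].any():
            raise ValueError("detections recorded in effort=none occasions")

    @property
    def n_individuals(self) -> int:
        return self.y.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.y.shape[1]

    @classmethod
    def build(
        cls,
        y: np.ndarray,
        f: np.ndarray,
        mass_z: np.ndarray,
        sex: np.ndarray,
        fed: np.ndarray,
        calendar: OccasionCalendar,
        snow_scaling: SnowScaling,
        tagging_dates=None,
    ) -> "EncounterData":
        f = np.asarray(f, dtype=np.int64)
        return cls(
            y=y,
            f=f,
            mass_z=np.asarray(mass_z, dtype=float),
            sex=np.asarray(sex, dtype=float),
            fed=np.asarray(fed, dtype=float),
            calendar=calendar,
            snow_x=snow_covariate(calendar.snow_days(), calendar, snow_scaling),
            snow_scaling=snow_scaling,
            season_idx=season_index_matrix(calendar, f, tagging_dates),
        )

    # -- I/O ---------------------------------------------------------------
    def encounters_frame(self) -> pd.DataFrame:
        """0/1 matrix with effort=none cells coded −9 (structurally unobservable)."""
        out = self.y.astype(np.int64).copy()
        out[:, self.calendar.effort() == "none"] = MISSING_CODE
        df = pd.DataFrame(out, columns=[f"occ{t + 1}" for t in range(self.n_occasions)])
        df.insert(0, "individual", np.arange(1, self.n_individuals + 1))
        return df

    def individuals_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual": np.arange(1, self.n_individuals + 1),
                "release_occasion": self.f + 1,
                "sex": self.sex.astype(int),
                "mass_z": self.mass_z,
                "fed": self.fed.astype(int),
            }
        )

    @classmethod
    def from_frames(
        cls,
        encounters: pd.DataFrame,
        individuals: pd.DataFrame,
        calendar: OccasionCalendar,
        snow_scaling: SnowScaling,
    ) -> "EncounterData":
        occ_cols = [c for c in encounters.columns if c.startswith("occ")]
        y = encounters[occ_cols].to_numpy()
        y = np.where(y == MISSING_CODE, 0, y)
        ind = individuals.sort_values("individual")
        return cls.build(
            y=y,
            f=ind["release_occasion"].to_numpy() - 1,
            mass_z=ind["mass_z"].to_numpy(),
            sex=ind["sex"].to_numpy(),
            fed=ind["fed"].to_numpy(),
            calendar=calendar,
            snow_scaling=snow_scaling,
        )


# ---------------------------------------------------------------------------
# Linear predictors
# ---------------------------------------------------------------------------

def survival_logit(
    params: ParameterVector,
    mass_z: float,
    sex: float,
    fed: float,
    season: str,
    snow_x: float,
    masks: SeasonMask = SeasonMask(),
) -> float:
    """Logit-scale biweekly survival for one individual in one occasion.

    Covariate effects contribute only in the seasons named by their mask.
    """
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}")
    s = SEASONS.index(season)
    eta = params.alpha_season[s] + params.beta_snow_surv * snow_x
    if season in masks.mass:
        eta += params.beta_mass * mass_z
    if season in masks.sex:
        eta += params.beta_sex * sex
    if season in masks.fed:
        eta += params.beta_fed * fed
    return float(eta)


def survival_logit_matrix(
    params: ParameterVector, data: EncounterData, masks: SeasonMask = SeasonMask()
) -> np.ndarray:
    """n×T matrix of logit survival; column t governs the interval t → t+1."""
    sidx = data.season_idx
    eta = params.alpha_season[sidx] + params.beta_snow_surv * data.snow_x[None, :]
    eta = eta + params.beta_mass * masks.indicator("mass")[sidx] * data.mass_z[:, None]
    eta = eta + params.beta_sex * masks.indicator("sex")[sidx] * data.sex[:, None]
    eta = eta + params.beta_fed * masks.indicator("fed")[sidx] * data.fed[:, None]
    return eta


def detection_prob(
    params: ParameterVector, effort: str, snow_x: float, eps_i: float = 0.0
) -> float:
    """Detection probability at one occasion: structurally 0 without effort."""
    if effort == "none":
        return 0.0
    base = params.p_full if effort == "full" else params.p_reduced
    return float(expit(logit(base) + params.beta_snow_det * snow_x + eps_i))


def detection_prob_matrix(params: ParameterVector, data: EncounterData) -> np.ndarray:
    """n×T detection probabilities, honouring the structural zeros."""
    effort = data.calendar.effort()
    base = np.where(effort == "full", params.p_full, params.p_reduced)
    eps = params.eps if params.eps is not None else np.zeros(data.n_individuals)
    eta = logit(base)[None, :] + params.beta_snow_det * data.snow_x[None, :] + eps[:, None]
    p = expit(eta)
    p[:, effort == "none"] = 0.0
    return p


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _check_history(history, phi_vec, p_vec):
    history = np.asarray(history, dtype=np.int64)
    phi_vec = np.asarray(phi_vec, dtype=float)
    p_vec = np.asarray(p_vec, dtype=float)
    L = len(history)
    if L < 1 or history[0] != 1:
        raise ValueError("history must start with the release detection (1)")
    if phi_vec.shape != (max(L - 1, 0),):
        raise ValueError("need one survival probability per interval (L-1)")
    if p_vec.shape != (L,):
        raise ValueError("need one detection probability per occasion (p[0] unused)")
    if ((phi_vec < 0) | (phi_vec > 1)).any() or ((p_vec < 0) | (p_vec > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    if (history[1:] == 1).any() and (p_vec[1:][history[1:] == 1] == 0).any():
        raise ValueError("detection recorded at an occasion with p = 0")
    return history, phi_vec, p_vec


def cjs_loglik_individual(history, phi_vec, p_vec) -> float:
    """Marginal CJS log-likelihood of one encounter history (forward recursion).

    ``history`` runs from the release occasion (index 0, value 1) to the end
    of the study; ``phi_vec[k]`` is survival over interval k → k+1 and
    ``p_vec[k]`` detection at occasion k (``p_vec[0]`` is unused because the
    model conditions on first release).  The latent alive/dead chain is
    marginalised exactly, summing over all death intervals at or after the
    last detection.
    """
    history, phi_vec, p_vec = _check_history(history, phi_vec, p_vec)
    la, ld = 0.0, -np.inf  # log P(data so far, alive / dead now)
    with np.errstate(divide="ignore"):
        lphi = np.log(phi_vec)
        l1mphi = np.log1p(-phi_vec)
        lp = np.log(p_vec)
        l1mp = np.log1p(-p_vec)
    for t in range(1, len(history)):
        obs = lp[t] if history[t] else l1mp[t]
        la_new = la + lphi[t - 1] + obs
        ld_new = np.logaddexp(ld, la + l1mphi[t - 1])
        if history[t]:
            ld_new = -np.inf
        la, ld = la_new, ld_new
    return float(np.logaddexp(la, ld))


def brute_force_loglik(history, phi_vec, p_vec) -> float:
    """Enumeration oracle: sum the history's probability over every death time.

    Death in interval d → d+1 (or survival to the end) has prior probability
    ∏φ up to d times (1 − φ_d), and the observation probability is a product
    of Bernoulli terms while alive and structural zeros after death.  Only
    suitable for short histories; exists to cross-check the forward recursion.
    """
    history, phi_vec, p_vec = _check_history(history, phi_vec, p_vec)
    L = len(history)
    total = 0.0
    for d in range(L):  # d = last occasion alive; d = L-1 includes survival to end
        if (history[d + 1 :] == 1).any():
            continue  # detections after death are impossible
        pr = 1.0
        for t in range(1, d + 1):  # survived interval t-1 -> t, observed at t
            pr *= phi_vec[t - 1]
            pr *= p_vec[t] if history[t] else 1.0 - p_vec[t]
        if d < L - 1:
            pr *= 1.0 - phi_vec[d]  # died in interval d -> d+1
        total += pr
    with np.errstate(divide="ignore"):
        return float(np.log(total))


def cjs_loglik_matrix(y, f, phi, p) -> np.ndarray:
    """Vectorised per-individual CJS log-likelihoods.

    ``y`` n×T detections, ``f`` 0-based releases, ``phi`` n×T survival for
    interval t → t+1 (column T−1 unused), ``p`` n×T detection.  Individuals
    contribute from their release occasion onwards; cells with p = 0 and y = 0
    contribute a factor of 1, so effort-free occasions are likelihood-neutral.
    """
    y = np.asarray(y, dtype=np.int64)
    f = np.asarray(f, dtype=np.int64)
    n, T = y.shape
    rows = np.arange(n)
    after = np.arange(T)[None, :] > f[:, None]
    if ((y == 1) & after & (p == 0)).any():
        raise ValueError("detection recorded at an occasion with p = 0")
    with np.errstate(divide="ignore"):
        lphi = np.log(phi)
        l1mphi = np.log1p(-phi)
        lp = np.log(p)
        l1mp = np.log1p(-p)
    la = np.where(f == 0, 0.0, -np.inf)
    ld = np.full(n, -np.inf)
    for t in range(1, T):
        obs = np.where(y[:, t] == 1, lp[:, t], l1mp[:, t])
        la_new = la + lphi[:, t - 1] + obs
        ld_new = np.logaddexp(ld, la + l1mphi[:, t - 1])
        ld_new = np.where(y[:, t] == 1, -np.inf, ld_new)
        la, ld = la_new, ld_new
        just_released = f == t
        la = np.where(just_released, 0.0, la)
        ld = np.where(just_released, -np.inf, ld)
    return np.logaddexp(la, ld)


def cjs_loglik_total(
    data: EncounterData, params: ParameterVector, masks: SeasonMask = SeasonMask()
) -> float:
    """Total log-likelihood: sum of individual marginal likelihoods.

    Conditional on the individual detection random effects carried in
    ``params.eps`` (zero if absent).
    """
    if data.n_individuals == 0:
        return 0.0
    phi = expit(survival_logit_matrix(params, data, masks))
    p = detection_prob_matrix(params, data)
    return float(cjs_loglik_matrix(data.y, data.f, phi, p).sum())
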