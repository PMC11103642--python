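"""Derived demographic quantities: from posterior draws to reportable tables.

Biweekly survival probabilities are powered up to season length (summer 4,
autumn 6, winter 10, spring 6 biweekly periods — one annual cycle of 26,
1 July to 30 June), multiplied into annual survival, decomposed into the
seasonal shares of first-year mortality, and propagated through 26-period
cohort trajectories.  Every quantity is computed per posterior draw and only
then summarised (median, central 95% credible interval): transforming a
posterior median instead would bias non-linear quantities such as powers and
products.

Winter scenarios are expressed as a composition of the 10 winter periods'
snow-day counts.  The mild scenario is snow-free; the harsh scenario follows
the worst winter observed in the study region: two periods of extreme, three
of high and three of intermediate snow cover plus two snow-free periods,
totalling 60 of 140 winter days (43%) under ≥1 cm of snow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .inference import PosteriorSamples
from .occasions import SEASONS
from .snow import SnowScaling

__all__ = [
    "SEASON_PERIODS",
    "SeasonLengths",
    "WinterComposition",
    "MILD_WINTER",
    "HARSH_WINTER",
    "season_survival",
    "winter_survival",
    "annual_survival",
    "mortality_partition",
    "relative_change",
    "DerivedDemography",
    "derive_demography",
    "cohort_trajectory",
    "summarize_posterior",
    "table_seasonal_survival",
    "table_mortality_partition",
]

#: Biweekly periods per season over one annual cycle (1 July – 30 June).
SEASON_PERIODS = {"summer": 4, "autumn": 6, "winter": 10, "spring": 6}


@dataclass(frozen=True)
class SeasonLengths:
    """Season lengths in biweekly periods; must tile the 26-period year."""

    summer: int = 4
    autumn: int = 6
    winter: int = 10
    spring: int = 6

    def __post_init__(self) -> None:
        if self.summer + self.autumn + self.winter + self.spring != 26:
            raise ValueError("season lengths must sum to 26 biweekly periods")

    def as_dict(self) -> dict[str, int]:
        return {s: getattr(self, s) for s in SEASONS}


@dataclass(frozen=True)
class WinterComposition:
    """Snow-day counts for the 10 winter periods of a scenario."""

    snow_days: tuple
    label: str

    def __post_init__(self) -> None:
        if len(self.snow_days) != SEASON_PERIODS["winter"]:
            raise ValueError("winter composition needs one value per winter period")
        if any(not 0 <= v <= 14 for v in self.snow_days):
            raise ValueError("per-period snow days must lie in [0, 14]")

    @property
    def total_days(self) -> int:
        return int(sum(self.snow_days))


MILD_WINTER = WinterComposition((0,) * 10, "mild")
#: 2 extreme + 3 high + 3 intermediate + 2 snow-free periods = 60 days.
HARSH_WINTER = WinterComposition((12, 12, 8, 8, 8, 4, 4, 4, 0, 0), "harsh")


def season_survival(phi_biweekly, n_periods: int):
    """Survival over a whole season: biweekly survival to the power of the
    season's length in biweekly periods."""
    if n_periods < 1:
        raise ValueError("n_periods must be at least 1")
    phi = np.asarray(phi_biweekly, dtype=float)
    if ((phi < 0) | (phi > 1)).any():
        raise ValueError("survival probabilities must lie in [0, 1]")
    out = phi**n_periods
    return float(out) if np.isscalar(phi_biweekly) else out


def winter_survival(alpha_winter, beta_snow_surv, composition: WinterComposition, scaling: SnowScaling):
    """Overwinter survival: product over the 10 winter periods of the
    biweekly survival implied by each period's snow-day count.

    ``alpha_winter``/``beta_snow_surv`` may be posterior draw vectors; the
    snow-day counts pass through the model's stored standardisation before
    entering the linear predictor.
    """
    z = scaling.transform(np.asarray(composition.snow_days, dtype=float))
    alpha = np.asarray(alpha_winter, dtype=float)
    beta = np.asarray(beta_snow_surv, dtype=float)
    per_period = expit(alpha[..., None] + beta[..., None] * z)
    out = per_period.prod(axis=-1)
    return float(out) if out.ndim == 0 else out


def annual_survival(seasonals):
    """Annual first-year survival: product of the four seasonal survivals
    (1 July to 30 June).  ``seasonals`` is length-4 in canonical season order
    (each entry may be a draw vector)."""
    s = [np.asarray(x, dtype=float) for x in seasonals]
    if len(s) != 4:
        raise ValueError("need four seasonal survival probabilities")
    out = s[0] * s[1] * s[2] * s[3]
    return float(out) if np.ndim(out) == 0 else out


def mortality_partition(seasonals):
    """Seasonal shares of first-year mortality, in percent.

    The share of season k is the probability of surviving to the start of
    season k and dying within it, relative to total first-year mortality:
    ``(S₁···S_{k−1})(1 − S_k) / (1 − S_annual) × 100``.  Shares sum to 100.
    Raises when there is no mortality at all.
    """
    s = [np.asarray(x, dtype=float) for x in seasonals]
    if len(s) != 4:
        raise ValueError("need four seasonal survival probabilities")
    annual = annual_survival(s)
    denom = 1.0 - annual
    if np.any(denom <= 0):
        raise ValueError("no mortality: partition undefined when all seasonal survivals are 1")
    shares = []
    alive = np.ones_like(s[0])
    for k in range(4):
        shares.append(100.0 * alive * (1.0 - s[k]) / denom)
        alive = alive * s[k]
    return np.stack(shares, axis=-1)


def relative_change(reference, alternative):
    """Percent reduction of ``alternative`` relative to ``reference``:
    ``100 × (reference − alternative) / reference``."""
    ref = np.asarray(reference, dtype=float)
    if np.any(ref == 0):
        raise ValueError("reference must be non-zero")
    out = 100.0 * (ref - np.asarray(alternative, dtype=float)) / ref
    return float(out) if np.ndim(out) == 0 else out


def _quantile_summary(x: np.ndarray) -> dict[str, float]:
    return {
        "median": float(np.median(x)),
        "lo95": float(np.quantile(x, 0.025)),
        "hi95": float(np.quantile(x, 0.975)),
    }


@dataclass
class DerivedDemography:
    """Per-draw derived quantities for the four scenario combinations.

    Keys of the per-draw dicts are ``(winter, group)`` with winter in
    {"mild", "harsh"} and group in {"natural", "fed"}.
    """

    seasonal: dict  # (winter, group) -> (draws, 4) seasonal survival
    annual: dict  # (winter, group) -> (draws,) annual survival
    partition: dict  # (winter, group) -> (draws, 4) mortality shares (%)

    def summary_annual(self, winter: str, group: str = "natural") -> dict[str, float]:
        return _quantile_summary(self.annual[(winter, group)])


def _seasonal_draws(
    samples: PosteriorSamples,
    scaling: SnowScaling,
    composition: WinterComposition,
    fed: bool,
    lengths: SeasonLengths,
) -> np.ndarray:
    """(draws, 4) seasonal survival for a bird of average mass of the given
    feeding group, applying the fitted season masks to the feeding effect."""
    alpha = samples.alpha_matrix()  # (draws, 4)
    masks = samples.meta.get("masks", {"fed": ["summer"]})
    fed_seasons = set(masks.get("fed", ["summer"]))
    beta_fed = samples.flat("beta_fed") if fed else np.zeros(alpha.shape[0])
    out = np.empty_like(alpha)
    for k, season in enumerate(SEASONS):
        eta = alpha[:, k].copy()
        if fed and season in fed_seasons:
            eta = eta + beta_fed
        n_per = getattr(lengths, season)
        if season == "winter":
            beta_snow = samples.flat("beta_snow_surv")
            if fed and season in fed_seasons:
                # feeding shifts every winter period's logit
                z = scaling.transform(np.asarray(composition.snow_days, dtype=float))
                per = expit(eta[:, None] + beta_snow[:, None] * z)
                out[:, k] = per.prod(axis=1)
            else:
                out[:, k] = winter_survival(alpha[:, k], beta_snow, composition, scaling)
        else:
            out[:, k] = season_survival(expit(eta), n_per)
    return out


def derive_demography(
    samples: PosteriorSamples,
    scaling: SnowScaling,
    lengths: SeasonLengths = SeasonLengths(),
    compositions: dict[str, WinterComposition] | None = None,
) -> DerivedDemography:
    """Compute all per-draw derived quantities for the scenario grid."""
    comps = compositions or {"mild": MILD_WINTER, "harsh": HARSH_WINTER}
    seasonal, annual, partition = {}, {}, {}
    for wlabel, comp in comps.items():
        for group, fed in (("natural", False), ("fed", True)):
            sdr = _seasonal_draws(samples, scaling, comp, fed, lengths)
            key = (wlabel, group)
            seasonal[key] = sdr
            annual[key] = annual_survival([sdr[:, 0], sdr[:, 1], sdr[:, 2], sdr[:, 3]])
            partition[key] = mortality_partition([sdr[:, 0], sdr[:, 1], sdr[:, 2], sdr[:, 3]])
    return DerivedDemography(seasonal=seasonal, annual=annual, partition=partition)


def cohort_trajectory(
    samples: PosteriorSamples,
    scaling: SnowScaling,
    winter: str = "mild",
    fed: bool = False,
    n0: int = 100,
    lengths: SeasonLengths = SeasonLengths(),
    compositions: dict[str, WinterComposition] | None = None,
) -> pd.DataFrame:
    """Expected number (out of ``n0``) of average-mass juveniles still alive
    after each of the 26 biweekly periods of the first year.

    Deterministic per-draw multiplication: each draw's scenario-specific
    biweekly survivals are applied period by period; the summaries are the
    median and the 2.5/97.5 percentiles across draws.
    """
    comps = compositions or {"mild": MILD_WINTER, "harsh": HARSH_WINTER}
    if winter not in comps:
        raise ValueError(f"unknown winter scenario {winter!r}")
    comp = comps[winter]
    alpha = samples.alpha_matrix()
    n_draws = alpha.shape[0]
    masks = samples.meta.get("masks", {"fed": ["summer"]})
    fed_seasons = set(masks.get("fed", ["summer"]))
    beta_fed = samples.flat("beta_fed")
    beta_snow = samples.flat("beta_snow_surv")
    biweekly = np.empty((n_draws, 26))
    col = 0
    for k, season in enumerate(SEASONS):
        n_per = getattr(lengths, season)
        for j in range(n_per):
            eta = alpha[:, k].copy()
            if fed and season in fed_seasons:
                eta += beta_fed
            if season == "winter":
                eta = eta + beta_snow * scaling.transform(float(comp.snow_days[j]))
            biweekly[:, col] = expit(eta)
            col += 1
    alive = n0 * np.cumprod(biweekly, axis=1)
    qs = np.quantile(alive, [0.5, 0.025, 0.975], axis=0)
    return pd.DataFrame(
        {
            "period": np.arange(1, 27),
            "alive_median": qs[0],
            "alive_lo95": qs[1],
            "alive_hi95": qs[2],
        }
    )


def summarize_posterior(samples: PosteriorSamples) -> pd.DataFrame:
    """Median and central 95% credible interval per scalar parameter."""
    rows = []
    for name in samples.draws:
        if name == "eps":
            continue
        x = samples.flat(name)
        rows.append({"parameter": name, **_quantile_summary(x)})
    return pd.DataFrame(rows)


def table_seasonal_survival(derived: DerivedDemography, group: str = "natural") -> pd.DataFrame:
    """Seasonal + annual survival with credible intervals, one row per
    season (winter split by scenario) and per annual scenario."""
    rows = []
    weeks = {"summer": 8, "autumn": 12, "winter": 20, "spring": 12}
    for k, season in enumerate(SEASONS):
        if season == "winter":
            for w in ("mild", "harsh"):
                rows.append(
                    {
                        "season": f"winter ({w})",
                        "duration_weeks": weeks[season],
                        **_quantile_summary(derived.seasonal[(w, group)][:, k]),
                    }
                )
        else:
            rows.append(
                {
                    "season": season,
                    "duration_weeks": weeks[season],
                    **_quantile_summary(derived.seasonal[("mild", group)][:, k]),
                }
            )
    for w in ("mild", "harsh"):
        rows.append(
            {
                "season": f"annual ({w} winter)",
                "duration_weeks": 52,
                **_quantile_summary(derived.annual[(w, group)]),
            }
        )
    return pd.DataFrame(rows)


def table_mortality_partition(derived: DerivedDemography) -> pd.DataFrame:
    """Seasonal shares (%) of first-year mortality, scenario × feeding group
    (posterior medians of the per-draw shares)."""
    cols = {}
    for group in ("natural", "fed"):
        for w in ("mild", "harsh"):
            med = np.median(derived.partition[(w, group)], axis=0)
            cols[f"{group}_{w}_winter"] = np.round(med, 1)
    return pd.DataFrame({"season": list(SEASONS), **cols})
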