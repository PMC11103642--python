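"""Daily snow-depth ingestion and the per-occasion snow-days covariate.

Snow cover limits a small owl's access to voles and invertebrates, so the
number of days with ≥1 cm snow cover within each biweekly occasion serves as
the winter-harshness covariate in both the survival and the detection linear
predictors.  Input is either a generic two-column CSV (``date, snow_cm``) or a
DWD "KL daily" climate-observation file (semicolon-separated, ``MESS_DATUM``
dates as YYYYMMDD, snow depth in ``SHK_TAG``, sentinel −999 for missing).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .occasions import OCCASION_DAYS, OccasionCalendar

__all__ = [
    "SnowSeries",
    "SnowScaling",
    "read_daily_snow",
    "snow_days_by_occasion",
    "standardize_snow",
    "winter_snow_scaling",
    "snow_covariate",
]

DWD_MISSING_SENTINEL = -999


@dataclass
class SnowSeries:
    """Daily snow depths (cm).  ``depth`` may contain NaN for missing days."""

    dates: np.ndarray  # datetime64[D], strictly increasing
    depth_cm: np.ndarray  # float, NaN = missing

    def __post_init__(self) -> None:
        self.dates = np.asarray(self.dates, dtype="datetime64[D]")
        self.depth_cm = np.asarray(self.depth_cm, dtype=float)
        if self.dates.shape != self.depth_cm.shape:
            raise ValueError("dates and depths must align")
        if len(self.dates) > 1 and not (np.diff(self.dates) > np.timedelta64(0, "D")).all():
            raise ValueError("dates must be strictly increasing (one record per day)")
        bad = self.depth_cm[~np.isnan(self.depth_cm)]
        if (bad < 0).any():
            raise ValueError("snow depth must be non-negative (use NaN for missing)")

    def __len__(self) -> int:
        return len(self.dates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates.astype(str), "snow_cm": self.depth_cm})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_daily_snow(path, dialect: str = "generic_csv") -> SnowSeries:
    """Read a daily snow-depth file into a :class:`SnowSeries`.

    ``dialect="generic_csv"`` expects columns ``date`` (ISO-8601) and
    ``snow_cm``; ``dialect="dwd_kl_daily"`` parses the semicolon-separated
    DWD KL daily format, mapping the −999 sentinel to missing.  Duplicated
    dates and negative non-sentinel depths are rejected.
    """
    if dialect == "generic_csv":
        df = pd.read_csv(path)
        if not {"date", "snow_cm"} <= set(df.columns):
            raise ValueError("generic_csv needs columns date, snow_cm")
        dates = pd.to_datetime(df["date"], format="ISO8601").dt.date
        depth = pd.to_numeric(df["snow_cm"])
    elif dialect == "dwd_kl_daily":
        df = pd.read_csv(path, sep=";", skipinitialspace=True)
        df.columns = [c.strip() for c in df.columns]
        if not {"MESS_DATUM", "SHK_TAG"} <= set(df.columns):
            raise ValueError("dwd_kl_daily needs columns MESS_DATUM, SHK_TAG")
        dates = pd.to_datetime(df["MESS_DATUM"].astype(str).str.strip(), format="%Y%m%d").dt.date
        depth = pd.to_numeric(df["SHK_TAG"], errors="raise").astype(float)
        depth = depth.mask(depth == DWD_MISSING_SENTINEL, np.nan)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if dates.duplicated().any():
        raise ValueError("duplicated dates in snow series")
    order = np.argsort(dates.to_numpy())
    return SnowSeries(
        np.asarray(dates.to_numpy()[order], dtype="datetime64[D]"),
        depth.to_numpy()[order],
    )


def snow_days_by_occasion(
    series: SnowSeries,
    calendar: OccasionCalendar,
    depth_threshold_cm: float = 1.0,
    missing: str = "error",
) -> np.ndarray:
    """Count days with snow depth ≥ threshold within each biweekly occasion.

    ``missing`` controls days without a record (or with a missing depth)
    inside the calendar span: ``"error"`` (strict, default) or ``"zero"``
    (treat as snow-free).  Returns an integer vector in ``[0, 14]`` per
    occasion.
    """
    if missing not in ("error", "zero"):
        raise ValueError("missing policy must be 'error' or 'zero'")
    qualifying = {
        d: bool(v >= depth_threshold_cm)
        for d, v in zip(series.dates.astype("datetime64[D]").astype(dt.date), series.depth_cm)
        if not np.isnan(v)
    }
    have = set(qualifying)
    counts = np.zeros(len(calendar), dtype=np.int64)
    for k, occ in enumerate(calendar):
        days = [occ.start_date + dt.timedelta(days=j) for j in range(OCCASION_DAYS)]
        gaps = [d for d in days if d not in have]
        if gaps and missing == "error":
            raise ValueError(
                f"occasion {occ.index}: {len(gaps)} day(s) without a snow record "
                f"(first gap {gaps[0]}); use missing='zero' to treat gaps as snow-free"
            )
        counts[k] = sum(qualifying.get(d, False) for d in days)
    return counts


@dataclass(frozen=True)
class SnowScaling:
    """Affine standardisation ``z = (snow_days − center) / scale`` with the
    metadata needed to invert it and to report coefficients on a named scale."""

    center: float
    scale: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def transform(self, snow_days) -> np.ndarray:
        return (np.asarray(snow_days, dtype=float) - self.center) / self.scale

    def inverse(self, z) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.scale + self.center


def standardize_snow(snow_days, center: float, scale: float) -> np.ndarray:
    """``z = (snow_days − center)/scale`` (scale must be positive)."""
    return SnowScaling(center, scale).transform(snow_days)


def winter_snow_scaling(snow_days, calendar: OccasionCalendar) -> SnowScaling:
    """Default scaling: z-score over the winter-season occasions only.

    Snow is structurally (near-)zero outside winter, so centring and scaling
    over all occasions would let the snow-free majority dominate; restricting
    to winter occasions gives the covariate mean 0 and SD 1 where it actually
    varies.
    """
    winter = calendar.seasons() == "winter"
    if not winter.any():
        raise ValueError("calendar has no winter occasions")
    vals = np.asarray(snow_days, dtype=float)[winter]
    sd = float(vals.std(ddof=0))
    if sd == 0:
        raise ValueError("winter snow-day counts are constant; scaling undefined")
    return SnowScaling(center=float(vals.mean()), scale=sd)


def snow_covariate(snow_days, calendar: OccasionCalendar, scaling: SnowScaling) -> np.ndarray:
    """Per-occasion covariate entering the linear predictors.

    Standardised snow days on winter occasions, exactly 0 elsewhere: the same
    variable enters both the survival and the detection predictor, and
    zeroing it outside winter keeps the summer/autumn/spring intercepts
    interpretable as baseline survival unperturbed by the snow term.
    """
    z = scaling.transform(snow_days)
    return np.where(calendar.seasons() == "winter", z, 0.0)
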