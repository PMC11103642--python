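"""Biweekly occasion calendar: the discrete time axis of the survival analysis.

Radio-tracking detections are aggregated into consecutive 14-day ("biweekly")
encounter occasions.  Each occasion carries a calendar season label, a
tracking-effort regime (``full`` / ``reduced`` / ``none``) and, once weather
data are attached, a count of snow-covered days.  Everything downstream — the
encounter matrix, the survival and detection predictors, the derived seasonal
quantities — is indexed by this calendar.

Occasion intervals are half-open ``[start, start + 14 days)`` and occasion
indices are 1-based in all external interfaces (CSV files, configs); internal
arrays are 0-based.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SEASONS",
    "EFFORT_REGIMES",
    "OCCASION_DAYS",
    "SeasonDefinition",
    "Occasion",
    "OccasionCalendar",
    "season_of_date",
    "build_occasion_calendar",
    "release_occasion",
    "study_effort_spec",
    "season_index_matrix",
]

#: Canonical season order used for intercept vectors everywhere.
SEASONS = ("summer", "autumn", "winter", "spring")

EFFORT_REGIMES = ("full", "reduced", "none")

#: Length of one encounter occasion in days.
OCCASION_DAYS = 14


@dataclass(frozen=True)
class SeasonDefinition:
    """Year-agnostic (month, day) windows defining the four seasons.

    The default windows are: summer 15 May–1 Aug (post-fledging), autumn
    2 Aug–23 Oct (natal dispersal), winter 24 Oct–12 Mar, spring
    13 Mar–15 Jun (first breeding).  Bounds are inclusive.  The spring and
    summer windows deliberately overlap by four weeks (15 May–15 Jun) so that
    the staggered fledging of one cohort and the first breeding of the
    previous cohort can both be accommodated; a date in the overlap resolves
    to ``summer`` by default and to ``spring`` only for an individual past its
    first 2 August (see :func:`season_index_matrix`).
    """

    summer: tuple[tuple[int, int], tuple[int, int]] = ((5, 15), (8, 1))
    autumn: tuple[tuple[int, int], tuple[int, int]] = ((8, 2), (10, 23))
    winter: tuple[tuple[int, int], tuple[int, int]] = ((10, 24), (3, 12))
    spring: tuple[tuple[int, int], tuple[int, int]] = ((3, 13), (6, 15))

    def window(self, season: str) -> tuple[tuple[int, int], tuple[int, int]]:
        return getattr(self, season)

    def contains(self, season: str, date: dt.date) -> bool:
        (m0, d0), (m1, d1) = self.window(season)
        lo, hi, x = (m0, d0), (m1, d1), (date.month, date.day)
        if lo <= hi:
            return lo <= x <= hi
        # window wraps the year end (winter)
        return x >= lo or x <= hi


DEFAULT_SEASONS = SeasonDefinition()


def season_of_date(
    date: dt.date,
    season_def: SeasonDefinition = DEFAULT_SEASONS,
    *,
    second_year: bool = False,
) -> str:
    """Season label of a calendar date.

    Dates in the deliberate spring/summer overlap (15 May–15 Jun under the
    defaults) resolve to ``summer`` unless ``second_year=True``, which
    expresses the cohort-year rule: for a bird tracked past its first
    2 August these late-spring dates belong to its first breeding spring.
    """
    hits = [s for s in SEASONS if season_def.contains(s, date)]
    if not hits:  # unreachable under the default windows, which tile the year
        raise ValueError(f"date {date} falls in no season window")
    if len(hits) == 1:
        return hits[0]
    if set(hits) == {"summer", "spring"}:
        return "spring" if second_year else "summer"
    raise ValueError(f"ambiguous season windows for {date}: {hits}")


@dataclass
class Occasion:
    """One 14-day encounter occasion: ``[start_date, start_date + 14 d)``."""

    index: int  # 1-based
    start_date: dt.date
    season: str
    effort: str = "full"
    snow_days: int = 0

    @property
    def end_date(self) -> dt.date:
        """Exclusive end of the interval."""
        return self.start_date + dt.timedelta(days=OCCASION_DAYS)

    @property
    def midpoint(self) -> dt.date:
        return self.start_date + dt.timedelta(days=OCCASION_DAYS // 2)

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ValueError(f"unknown season {self.season!r}")
        if self.effort not in EFFORT_REGIMES:
            raise ValueError(f"unknown effort regime {self.effort!r}")
        if not 0 <= self.snow_days <= OCCASION_DAYS:
            raise ValueError(f"snow_days must be in [0, {OCCASION_DAYS}]")


@dataclass
class OccasionCalendar:
    """Ordered, contiguous sequence of biweekly occasions."""

    occasions: list[Occasion]
    season_def: SeasonDefinition = field(default=DEFAULT_SEASONS)

    def __post_init__(self) -> None:
        for k, occ in enumerate(self.occasions):
            if occ.index != k + 1:
                raise ValueError("occasion indices must be 1..T with no gaps")
            if k and occ.start_date != self.occasions[k - 1].end_date:
                raise ValueError("occasions must be contiguous 14-day blocks")

    def __len__(self) -> int:
        return len(self.occasions)

    def __iter__(self):
        return iter(self.occasions)

    def __getitem__(self, k: int) -> Occasion:
        return self.occasions[k]

    @property
    def origin_date(self) -> dt.date:
        return self.occasions[0].start_date

    @property
    def end_date(self) -> dt.date:
        """Exclusive end of the whole calendar span."""
        return self.occasions[-1].end_date

    # -- array views ------------------------------------------------------
    def seasons(self) -> np.ndarray:
        return np.array([o.season for o in self.occasions])

    def season_index(self) -> np.ndarray:
        """Per-occasion index into :data:`SEASONS` (calendar-level labels)."""
        lut = {s: i for i, s in enumerate(SEASONS)}
        return np.array([lut[o.season] for o in self.occasions], dtype=np.int64)

    def effort(self) -> np.ndarray:
        return np.array([o.effort for o in self.occasions])

    def snow_days(self) -> np.ndarray:
        return np.array([o.snow_days for o in self.occasions], dtype=np.int64)

    def set_snow_days(self, counts) -> None:
        counts = np.asarray(counts)
        if counts.shape != (len(self),):
            raise ValueError("need one snow-day count per occasion")
        for occ, c in zip(self.occasions, counts):
            occ.snow_days = int(c)

    def effort_counts(self) -> dict[str, int]:
        eff = self.effort()
        return {r: int((eff == r).sum()) for r in EFFORT_REGIMES}

    # -- I/O ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "occasion": [o.index for o in self.occasions],
                "start_date": [o.start_date.isoformat() for o in self.occasions],
                "season": [o.season for o in self.occasions],
                "effort": [o.effort for o in self.occasions],
                "snow_days": [o.snow_days for o in self.occasions],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OccasionCalendar":
        occs = [
            Occasion(
                index=int(r.occasion),
                start_date=dt.date.fromisoformat(str(r.start_date)),
                season=str(r.season),
                effort=str(r.effort),
                snow_days=int(r.snow_days),
            )
            for r in df.itertuples()
        ]
        return cls(occs)

    @classmethod
    def from_csv(cls, path) -> "OccasionCalendar":
        return cls.from_frame(pd.read_csv(path))


def build_occasion_calendar(
    origin_date: dt.date,
    n_occasions: int,
    effort_spec: dict[int, str] | None = None,
    season_def: SeasonDefinition = DEFAULT_SEASONS,
) -> OccasionCalendar:
    """Construct a contiguous calendar of ``n_occasions`` biweekly occasions.

    Parameters
    ----------
    origin_date
        Start of occasion 1 (its interval is ``[origin, origin + 14 d)``).
    n_occasions
        Number of occasions (``T``).
    effort_spec
        Optional map of 1-based occasion index to effort regime; unlisted
        occasions are ``full``.
    season_def
        Season windows; each occasion's season is the season of its midpoint
        date, which breaks ties for intervals straddling a season boundary.
    """
    if n_occasions < 1:
        raise ValueError("n_occasions must be positive")
    effort_spec = dict(effort_spec or {})
    for idx, regime in effort_spec.items():
        if not 1 <= idx <= n_occasions:
            raise ValueError(f"effort_spec index {idx} outside 1..{n_occasions}")
        if regime not in EFFORT_REGIMES:
            raise ValueError(f"unknown effort regime {regime!r}")
    occs = []
    for k in range(n_occasions):
        start = origin_date + dt.timedelta(days=OCCASION_DAYS * k)
        mid = start + dt.timedelta(days=OCCASION_DAYS // 2)
        occs.append(
            Occasion(
                index=k + 1,
                start_date=start,
                season=season_of_date(mid, season_def),
                effort=effort_spec.get(k + 1, "full"),
            )
        )
    return OccasionCalendar(occs, season_def=season_def)


def release_occasion(tagging_date: dt.date, calendar: OccasionCalendar) -> int:
    """1-based occasion whose half-open interval contains ``tagging_date``."""
    if not calendar.origin_date <= tagging_date < calendar.end_date:
        raise ValueError(
            f"tagging date {tagging_date} outside calendar span "
            f"[{calendar.origin_date}, {calendar.end_date})"
        )
    offset = (tagging_date - calendar.origin_date).days
    return offset // OCCASION_DAYS + 1


def study_effort_spec(calendar: OccasionCalendar) -> dict[int, str]:
    """Default effort layout emulating the field study's tracking gaps.

    Tracking was suspended entirely for four occasions spanning the late part
    of the first winter into the following early spring, and reduced for three
    occasions in the middle of the first winter and three at the end of the
    second winter.  This helper locates those occasions on an arbitrary
    calendar by its winter runs and returns the index→regime map (4 ``none``,
    6 ``reduced``) for :func:`build_occasion_calendar`.
    """
    seasons = calendar.seasons()
    runs: list[list[int]] = []
    for k, s in enumerate(seasons):
        if s == "winter":
            if runs and runs[-1][-1] == k - 1:
                runs[-1].append(k)
            else:
                runs.append([k])
    if len(runs) < 2 or len(runs[0]) < 8 or len(runs[1]) < 3:
        raise ValueError("calendar too short for the study effort layout")
    spec: dict[int, str] = {}
    r1 = runs[0]
    mid = len(r1) // 2
    for k in r1[mid - 1 : mid + 2]:  # mid-winter of year 1: reduced
        spec[k + 1] = "reduced"
    # last two winter occasions of year 1 plus the next two (early spring): none
    for k in range(r1[-1] - 1, r1[-1] + 3):
        spec[k + 1] = "none"
    for k in runs[1][-3:]:  # late winter of year 2: reduced
        spec[k + 1] = "reduced"
    if sorted(spec.values()).count("none") != 4 or list(spec.values()).count("reduced") != 6:
        raise ValueError("calendar too short for the study effort layout")
    return spec


def season_index_matrix(
    calendar: OccasionCalendar,
    release_idx: np.ndarray,
    tagging_dates: list[dt.date] | None = None,
) -> np.ndarray:
    """Per-individual season index for every occasion, shape ``(n, T)``.

    Implements the cohort-year resolution of the four-week spring/summer
    overlap: an occasion whose midpoint falls in the overlap counts as
    ``summer`` for birds not yet past their first 2 August (their
    post-fledging period) and as ``spring`` afterwards (their first breeding
    season).  Outside the overlap the calendar-level label applies to
    everyone.

    ``release_idx`` is 0-based; ``tagging_dates`` defaults to the start date
    of each bird's release occasion.
    """
    T = len(calendar)
    n = len(release_idx)
    base = calendar.season_index()
    out = np.tile(base, (n, 1))
    lut = {s: i for i, s in enumerate(SEASONS)}
    sd = calendar.season_def
    overlap = np.array(
        [
            sd.contains("summer", o.midpoint) and sd.contains("spring", o.midpoint)
            for o in calendar
        ]
    )
    if not overlap.any():
        return out
    if tagging_dates is None:
        tagging_dates = [calendar[int(f)].start_date for f in release_idx]
    (m1, d1) = sd.window("summer")[1]  # end of summer window (2 Aug boundary)
    for i, tag in enumerate(tagging_dates):
        first_autumn = dt.date(tag.year, m1, d1) + dt.timedelta(days=1)
        if first_autumn <= tag:
            first_autumn = dt.date(tag.year + 1, m1, d1) + dt.timedelta(days=1)
        for t in np.flatnonzero(overlap):
            if calendar[int(t)].midpoint >= first_autumn:
                out[i, t] = lut["spring"]
    return out
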