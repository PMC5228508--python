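"""Seasonal period calendar.

The analysis discretises time into calendar quarters: winter (January--March),
spring (April--June), summer (July--September) and autumn (October--December).
Periods are indexed 0, 1, 2, ... from the winter of the calendar's first year,
so there are exactly four periods per year and ``period // 4`` recovers the
year offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SEASONS: tuple[str, ...] = ("winter", "spring", "summer", "autumn")

#: Species-specific spawning seasons: Bull Trout ascend tributaries in
#: late summer, the large lacustrine Rainbow Trout spawn in spring.
SPAWN_SEASON: dict[str, str] = {
    "BullTrout": "summer",
    "RainbowTrout": "spring",
}


@dataclass(frozen=True)
class PeriodCalendar:
    """Contiguous, totally ordered sequence of seasonal periods.

    Parameters
    ----------
    start_year : int
        Calendar year of period 0 (a winter period).
    n_years : int
        Number of whole years covered; the calendar has ``4 * n_years``
        periods.
    """

    start_year: int
    n_years: int

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ValueError("calendar must span at least one year")

    @property
    def n_periods(self) -> int:
        return 4 * self.n_years

    @property
    def end_year(self) -> int:
        return self.start_year + self.n_years - 1

    def season(self, t: int) -> str:
        self._check(t)
        return SEASONS[t % 4]

    def year(self, t: int) -> int:
        self._check(t)
        return self.start_year + t // 4

    def years(self) -> np.ndarray:
        """Calendar year of every period, shape ``(n_periods,)``."""
        return self.start_year + np.arange(self.n_periods) // 4

    def seasons(self) -> np.ndarray:
        return np.array([SEASONS[t % 4] for t in range(self.n_periods)])

    def start(self, t: int) -> pd.Timestamp:
        self._check(t)
        return pd.Timestamp(year=self.year(t), month=3 * (t % 4) + 1, day=1)

    def end(self, t: int) -> pd.Timestamp:
        """Last calendar day of period ``t`` (periods are closed date ranges)."""
        self._check(t)
        if t + 1 < self.n_periods:
            return self.start(t + 1) - pd.Timedelta(days=1)
        return pd.Timestamp(year=self.year(t), month=12, day=31)

    def period_of(self, date) -> int:
        ts = pd.Timestamp(date)
        t = (ts.year - self.start_year) * 4 + (ts.month - 1) // 3
        if t < 0 or t >= self.n_periods:
            raise ValueError(f"date {ts.date()} outside calendar "
                             f"{self.start_year}-{self.end_year}")
        return t

    def period_of_many(self, dates) -> np.ndarray:
        dates = pd.DatetimeIndex(dates)
        t = (dates.year - self.start_year) * 4 + (dates.month - 1) // 3
        t = np.asarray(t)
        if ((t < 0) | (t >= self.n_periods)).any():
            bad = dates[(t < 0) | (t >= self.n_periods)]
            raise ValueError(f"dates outside calendar: {list(bad[:5])}")
        return t

    def season_window(self, year: int, season: str) -> tuple[pd.Timestamp, pd.Timestamp]:
        """Closed date range of one season in one calendar year."""
        q = SEASONS.index(season)
        t = (year - self.start_year) * 4 + q
        return self.start(t), self.end(t)

    def _check(self, t: int) -> None:
        if t < 0 or t >= self.n_periods:
            raise ValueError(f"period {t} outside 0..{self.n_periods - 1}")

    def __len__(self) -> int:
        return self.n_periods
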