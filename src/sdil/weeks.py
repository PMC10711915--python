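"""Weekly calendar for the levy evaluation.

The study runs on consecutive 7-day weeks. Two fixed anchors matter: the levy
was announced on 16 March 2016 and came into force on 6 April 2018. The default
calendar places 107 complete weeks before the announcement week and 52 weeks
after the implementation week, spanning roughly March 2014 to March 2019.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd
from dateutil.easter import easter

ANNOUNCEMENT_DATE = date(2016, 3, 16)
IMPLEMENTATION_DATE = date(2018, 4, 6)

#: Annual period in weeks (365.25 / 7); avoids seasonal drift over five years.
WEEKS_PER_YEAR = 365.25 / 7.0


def monday_of(day: date) -> date:
    """The Monday on or before ``day`` (weeks run Monday..Sunday)."""
    return day - timedelta(days=day.weekday())


@dataclass(frozen=True)
class Calendar:
    """A grid of consecutive weeks with the two interruption indices."""

    start_date: date
    n_weeks: int
    announcement_week: int
    implementation_week: int

    def __post_init__(self) -> None:
        if not (0 < self.announcement_week < self.implementation_week < self.n_weeks):
            raise ValueError(
                "require 0 < announcement_week < implementation_week < n_weeks, got "
                f"{self.announcement_week}, {self.implementation_week}, {self.n_weeks}"
            )

    @property
    def week_starts(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(
            [pd.Timestamp(self.start_date) + pd.Timedelta(days=7 * i) for i in range(self.n_weeks)]
        )

    def week_index_of(self, day: date) -> int:
        """Index of the week containing ``day`` (error if outside the grid)."""
        offset = (monday_of(day) - monday_of(self.start_date)).days // 7
        if not 0 <= offset < self.n_weeks:
            raise ValueError(f"{day} is outside the calendar")
        return offset


def default_calendar(pre_announcement_weeks: int = 107, post_implementation_weeks: int = 52) -> Calendar:
    """Study calendar anchored on the announcement and implementation dates.

    ``pre_announcement_weeks`` defaults to the study's 107 complete weeks of
    pre-announcement data.
    """
    ann_monday = monday_of(ANNOUNCEMENT_DATE)
    start = ann_monday - timedelta(weeks=pre_announcement_weeks)
    impl_week = (monday_of(IMPLEMENTATION_DATE) - start).days // 7
    n_weeks = impl_week + post_implementation_weeks
    return Calendar(
        start_date=start,
        n_weeks=n_weeks,
        announcement_week=pre_announcement_weeks,
        implementation_week=impl_week,
    )


def christmas_indicator(week_starts: pd.DatetimeIndex) -> np.ndarray:
    """1.0 for weeks starting in December or January (the Christmas period)."""
    return np.asarray(week_starts.month.isin([12, 1]), dtype=float)


def easter_indicator(week_starts: pd.DatetimeIndex) -> np.ndarray:
    """1.0 for the week containing Easter Sunday."""
    out = np.zeros(len(week_starts))
    for i, ws in enumerate(week_starts):
        sunday = ws + pd.Timedelta(days=6)
        for year in {ws.year, sunday.year}:
            if ws <= pd.Timestamp(easter(year)) <= sunday:
                out[i] = 1.0
    return out
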