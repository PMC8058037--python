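"""Holiday and sporting-event calendars for temporal features.

Holidays are computed from US federal-holiday rules (fixed dates plus
nth-weekday rules) with New Year's Eve added, for any year range.  The
sports table lists championship-final dates (Super Bowl, World Series, NBA
finals) with winner/loser states for the study window; both calendars are
overridable on the featurizer.
"""
from __future__ import annotations

import datetime as dt
from typing import Iterable

import pandas as pd


def _nth_weekday(year: int, month: int, weekday: int, n: int) -> dt.date:
    """n-th (1-based) `weekday` (Mon=0) of a month; n=-1 means last."""
    if n > 0:
        d = dt.date(year, month, 1)
        offset = (weekday - d.weekday()) % 7
        return d + dt.timedelta(days=offset + 7 * (n - 1))
    d = (dt.date(year + 1, 1, 1) if month == 12 else dt.date(year, month + 1, 1))
    d -= dt.timedelta(days=1)
    return d - dt.timedelta(days=(d.weekday() - weekday) % 7)


def us_holidays(years: Iterable[int]) -> set[dt.date]:
    """US federal holidays plus New Year's Eve, by calendar rule."""
    out: set[dt.date] = set()
    for y in years:
        out.update({
            dt.date(y, 1, 1),                      # New Year's Day
            _nth_weekday(y, 1, 0, 3),              # MLK Day
            _nth_weekday(y, 2, 0, 3),              # Presidents' Day
            _nth_weekday(y, 5, 0, -1),             # Memorial Day
            dt.date(y, 7, 4),                      # Independence Day
            _nth_weekday(y, 9, 0, 1),              # Labor Day
            _nth_weekday(y, 10, 0, 2),             # Columbus Day
            dt.date(y, 11, 11),                    # Veterans Day
            _nth_weekday(y, 11, 3, 4),             # Thanksgiving
            dt.date(y, 12, 25),                    # Christmas
            dt.date(y, 12, 31),                    # New Year's Eve
        })
    return out


#: Championship-final dates with winner/loser home states, 2013-2017.
#: World Series / NBA finals use the deciding-game date.
SPORTS_EVENTS = pd.DataFrame(
    [
        ("2013-02-03", "superbowl", "MD", "CA"),
        ("2013-06-20", "nba_final", "FL", "TX"),
        ("2013-10-30", "world_series", "MA", "MO"),
        ("2014-02-02", "superbowl", "WA", "CO"),
        ("2014-06-15", "nba_final", "TX", "FL"),
        ("2014-10-29", "world_series", "CA", "MO"),
        ("2015-02-01", "superbowl", "MA", "WA"),
        ("2015-06-16", "nba_final", "CA", "OH"),
        ("2015-11-01", "world_series", "MO", "NY"),
        ("2016-02-07", "superbowl", "CO", "NC"),
        ("2016-06-19", "nba_final", "OH", "CA"),
        ("2016-11-02", "world_series", "IL", "OH"),
        ("2017-02-05", "superbowl", "MA", "GA"),
        ("2017-06-12", "nba_final", "CA", "OH"),
    ],
    columns=["date", "event", "winner_state", "loser_state"],
)
SPORTS_EVENTS["date"] = pd.to_datetime(SPORTS_EVENTS["date"]).dt.date
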