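"""Reporting layer: day-convention conversion, critical-period intervals
and weight-surface export.

The headline report quantity is the lag between a species' critical
temperature period and its breeding: the day count from the close of the
best-supported window to the species' multi-year mean clutch initiation
date, on the non-leap calendar.  :data:`PUBLISHED_CRITICAL_PERIODS` carries
the published estimates for the interior British Columbia resident
cavity-nester community, against which the interval arithmetic can be
checked (e.g. the hairy woodpecker's Jan 7-Feb 19 window closes 78 days
before its May 8 mean lay date).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .daycal import convert_day_origin, day_interval, format_day, parse_monthday
from .windows import WindowSpec, WindowResult, weight_surface  # noqa: F401 - re-export

#: Published best maximum-temperature windows and multi-year mean lay dates
#: ('MM-DD' strings) for the six responsive species of the interior British
#: Columbia cavity-nester community.
PUBLISHED_CRITICAL_PERIODS = {
    "mountain_chickadee": ("03-07", "05-20", "05-24"),
    "black_capped_chickadee": ("03-04", "04-13", "05-24"),
    "red_breasted_nuthatch": ("03-09", "04-05", "05-28"),
    "downy_woodpecker": ("04-19", "05-19", "05-31"),
    "hairy_woodpecker": ("01-07", "02-19", "05-08"),
    "american_three_toed_woodpecker": ("04-28", "05-08", "05-26"),
}


@dataclass
class CriticalPeriodSummary:
    """Best window, mean lay date and the lag between them for one species."""

    species: str
    best_window: WindowSpec
    mean_lay_date: int
    interval_days: int

    def as_row(self) -> dict:
        return {
            "species": self.species,
            "window_open": format_day(self.best_window.open),
            "window_close": format_day(self.best_window.close),
            "window_width": self.best_window.width,
            "mean_lay_date": format_day(self.mean_lay_date),
            "interval_days": self.interval_days,
        }


def critical_period_summary(species: str, best_window: WindowSpec,
                            mean_lay_date: int) -> CriticalPeriodSummary:
    """Interval from the window close to the mean lay date (days)."""
    return CriticalPeriodSummary(
        species=species, best_window=best_window,
        mean_lay_date=int(mean_lay_date),
        interval_days=day_interval(best_window.close, int(mean_lay_date)),
    )


def published_interval_table() -> pd.DataFrame:
    """Critical-period lag table recomputed from the published windows and
    mean lay dates (one row per species, ``interval_days`` column)."""
    rows = []
    for sp, (open_md, close_md, lay_md) in PUBLISHED_CRITICAL_PERIODS.items():
        w = WindowSpec(parse_monthday(open_md), parse_monthday(close_md))
        rows.append(critical_period_summary(sp, w, parse_monthday(lay_md)).as_row())
    return pd.DataFrame(rows)


def to_days_after_april1(day_index):
    """Convenience conversion for plotting (day 1 = April 1)."""
    return convert_day_origin(day_index, "jan1", "apr1")


def plot_weight_surface(surface: pd.DataFrame, best=None, ax=None):
    """Heat-map of Akaike weight by window open/close day (optional)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    grid = surface.pivot(index="open_day", columns="close_day", values="weight")
    im = ax.pcolormesh(grid.columns, grid.index, grid.to_numpy(), shading="nearest")
    ax.set_xlabel("window close (day index)")
    ax.set_ylabel("window open (day index)")
    if best is not None:
        ax.plot([best.close], [best.open], marker="s", mfc="none", mec="red")
    ax.figure.colorbar(im, ax=ax, label="Akaike weight")
    return ax
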