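"""Exhaustive calendar-window search for the climate signal in lay dates.

Every contiguous window of at least ``min_width`` days between the scan range
bounds (by default November 1 of the previous year to June 1 of the breeding
year) is a candidate; the window covariate is the arithmetic mean of one
daily weather variable over the window, shared by all nests of a breeding
year (absolute calendar windows).  Each candidate is ranked by the AICc of
the mixed model ``initiation ~ window_mean + (1 | year)`` fit by maximum
likelihood, and relative support across the candidate set is expressed as
Akaike weights (the support surface over open/close days).

Because every AICc comparison over thousands of windows is also an implicit
multiple test, a response-randomization guard estimates how much AICc
improvement over the intercept-only model arises by chance: initiation dates
are permuted across records (breaking the date-year-weather linkage), the
full scan is re-run per permutation, and the observed improvement is ranked
within the null distribution.  Results with p > 0.05 are flagged spurious.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import lmm
from .daycal import format_day, parse_monthday
from .simulate import WeatherSeries

DEFAULT_RANGE_START = parse_monthday("11-01") - 365   # Nov 1, previous year
DEFAULT_RANGE_END = parse_monthday("06-01")           # Jun 1, breeding year


@dataclass(frozen=True)
class WindowSpec:
    """One candidate calendar window (day indices, close inclusive)."""

    open: int
    close: int
    variable: str = "tmax"
    aggregate: str = "mean"

    def __post_init__(self):
        if self.close < self.open:
            raise ValueError("window close precedes open")

    @property
    def width(self) -> int:
        return self.close - self.open + 1

    def label(self) -> str:
        return f"{format_day(self.open)}-{format_day(self.close)}"

    def jaccard(self, other: "WindowSpec") -> float:
        """Overlap / union of the two day ranges."""
        inter = min(self.close, other.close) - max(self.open, other.open) + 1
        union = max(self.close, other.close) - min(self.open, other.open) + 1
        return max(0, inter) / union


def enumerate_windows(range_start: int = DEFAULT_RANGE_START,
                      range_end: int = DEFAULT_RANGE_END,
                      min_width: int = 10, step: int = 1,
                      variable: str = "tmax") -> list[WindowSpec]:
    """All contiguous [open, close] windows of width >= min_width.

    Opens and closes lie on a ``step``-day grid anchored at the range bounds;
    the full-range window is always included.
    """
    if min_width < 1:
        raise ValueError("min_width must be >= 1")
    if range_end - range_start + 1 < min_width:
        raise ValueError("scan range shorter than the minimum window width")
    out = []
    for o in range(range_start, range_end - min_width + 2, step):
        for c in range(o + min_width - 1, range_end + 1, step):
            out.append(WindowSpec(o, c, variable))
    full = WindowSpec(range_start, range_end, variable)
    if full not in out:
        out.append(full)
    return out


def window_covariate(weather: WeatherSeries, window: WindowSpec,
                     year: int) -> float:
    """Mean of the window's weather variable over its days for one breeding
    year (prior-year day indices resolve into the previous calendar year).
    Missing days raise with the dates named; there is no gap-filling."""
    if window.aggregate == "mean":
        return weather.window_mean(window.variable, window.open, window.close, year)
    if window.aggregate == "sum":
        return float(weather.daily_values(window.variable, window.open,
                                          window.close, year).sum())
    raise ValueError(f"unknown aggregate {window.aggregate!r}")


def _covariate_matrix(weather: WeatherSeries, windows: list[WindowSpec],
                      years: np.ndarray) -> np.ndarray:
    """(W x J) window-mean matrix via cumulative sums of the daily series."""
    lo = min(w.open for w in windows)
    hi = max(w.close for w in windows)
    variable = windows[0].variable
    daily = np.stack([weather.daily_values(variable, lo, hi, int(y))
                      for y in years], axis=1)            # (days x J)
    csum = np.concatenate([np.zeros((1, len(years))), np.cumsum(daily, axis=0)])
    opens = np.array([w.open - lo for w in windows])
    closes = np.array([w.close - lo + 1 for w in windows])
    sums = csum[closes] - csum[opens]
    if any(w.aggregate == "sum" for w in windows):
        widths = np.where([w.aggregate == "sum" for w in windows], 1.0,
                          (closes - opens).astype(float))
    else:
        widths = (closes - opens).astype(float)
    return sums / widths[:, None]


@dataclass
class WindowResult:
    """Fitted summary of one candidate window."""

    window: WindowSpec
    aicc: float
    delta_aicc: float
    weight: float
    slope: float
    n: int


@dataclass
class RandomizationReport:
    """Type-I-error guard for a completed scan.

    ``observed_stat`` is the AICc improvement of the best window over the
    intercept-only model; ``p_value`` its rank within the permutation null.
    The scan is flagged spurious when p > 0.05.
    """

    observed_stat: float
    null_stats: np.ndarray
    p_value: float

    @property
    def spurious(self) -> bool:
        return self.p_value > 0.05


class ClimateWindowScanner(BaseEstimator):
    """Sliding-window search estimator.

    Parameters mirror the scan configuration: weather ``variable``, scan
    range day indices, minimum window width and day step.  ``fit`` takes the
    initiation data for one species (DataFrame with ``year`` and
    ``initiation`` columns) plus the weather series, and exposes

    - ``results_`` : list of :class:`WindowResult`, AICc-ordered input order
    - ``best_`` : the minimum-AICc window (ties: shorter, then earlier open)
    - ``null_aicc_`` : AICc of the intercept-only model
    - ``weights_`` : Akaike weights over the scanned set (sum to 1)
    """

    def __init__(self, variable: str = "tmax",
                 range_start: int = DEFAULT_RANGE_START,
                 range_end: int = DEFAULT_RANGE_END,
                 min_width: int = 10, step: int = 1,
                 min_nests_per_year: int = 2):
        self.variable = variable
        self.range_start = range_start
        self.range_end = range_end
        self.min_width = min_width
        self.step = step
        self.min_nests_per_year = min_nests_per_year

    def _prepare(self, dates: pd.DataFrame):
        counts = dates.groupby("year").size()
        keep = counts[counts >= self.min_nests_per_year].index
        if len(keep) < 3:
            raise ValueError(
                f"need >= 3 years with >= {self.min_nests_per_year} nests, "
                f"got {len(keep)}")
        sub = dates[dates["year"].isin(keep)]
        return (sub["initiation"].to_numpy(dtype=float),
                sub["year"].to_numpy(dtype=int))

    def fit(self, dates: pd.DataFrame, weather: WeatherSeries) -> "ClimateWindowScanner":
        y, year = self._prepare(dates)
        self.windows_ = enumerate_windows(self.range_start, self.range_end,
                                          self.min_width, self.step,
                                          self.variable)
        stats = lmm.GroupStats.from_arrays(y, year)
        C = _covariate_matrix(weather, self.windows_, stats.groups)
        self._scan_stats, self._scan_C = stats, C
        self._y_cache = (y, year)
        self._fit_from_stats(stats, C)
        return self

    def _fit_from_stats(self, stats, C):
        scan = lmm.scan_deviances(stats, C)
        aicc = lmm.aicc_from_deviance(scan["deviance"], k=4, n=stats.n_total)
        valid = np.isfinite(aicc)
        if not valid.all():
            warnings.warn(f"{(~valid).sum()} window fits did not converge; "
                          "excluded from Akaike weights")
        weights = lmm.akaike_weights(np.where(valid, aicc, np.inf))
        best_aicc = aicc[valid].min()
        # tie-break: minimum AICc, then shorter window, then earlier open
        order = sorted(
            np.flatnonzero(valid),
            key=lambda i: (round(aicc[i], 9), self.windows_[i].width,
                           self.windows_[i].open))
        b = order[0]
        null = lmm.fit_intercept_only_from_stats(stats)
        self.null_aicc_ = null.aicc
        self.weights_ = weights
        self.aicc_ = aicc
        self.results_ = [
            WindowResult(w, float(aicc[i]), float(aicc[i] - best_aicc),
                         float(weights[i]), float(scan["slope"][i]),
                         stats.n_total)
            for i, w in enumerate(self.windows_)
        ]
        self.best_ = self.results_[b]
        self.observed_stat_ = float(self.null_aicc_ - self.best_.aicc)
        return self

    # -- randomization Type-I guard ----------------------------------------
    def randomization_test(self, n_rand: int = 100, seed: int = 0,
                           unit: str = "years") -> RandomizationReport:
        """Re-run the scan ``n_rand`` times on randomized data;
        p = (1 + #{S_null >= S_obs}) / (n_rand + 1) where S is the
        best-window AICc improvement over the intercept-only model.

        ``unit='years'`` (default) permutes the window covariates across
        years, which preserves the response's year-level variance structure
        while severing the date-weather linkage; since the covariate is
        year-constant, years are the exchangeable unit and the test stays
        calibrated even when real year random effects exist.
        ``unit='records'`` permutes initiation dates across records instead
        (this also destroys the year clustering, so the null is lighter than
        the observed statistic on strongly year-structured data).
        """
        if not hasattr(self, "best_"):
            raise RuntimeError("run fit() before the randomization test")
        if n_rand < 20:
            warnings.warn(f"n_rand = {n_rand} gives an unstable p-value")
        if unit not in ("years", "records"):
            raise ValueError(f"unknown permutation unit {unit!r}")
        rng = np.random.default_rng(seed)
        stats, C = self._scan_stats, self._scan_C
        y, year = self._y_cache
        null_stats = np.empty(n_rand)
        for r in range(n_rand):
            if unit == "years":
                perm = rng.permutation(C.shape[1])
                s, Cp = stats, C[:, perm]
            else:
                s = lmm.GroupStats.from_arrays(rng.permutation(y), year)
                Cp = C
            scan = lmm.scan_deviances(s, Cp)
            aicc = lmm.aicc_from_deviance(scan["deviance"], k=4, n=s.n_total)
            null = lmm.fit_intercept_only_from_stats(s)
            null_stats[r] = null.aicc - np.nanmin(aicc)
        obs = self.observed_stat_
        p = (1.0 + np.sum(null_stats >= obs)) / (n_rand + 1.0)
        self.randomization_ = RandomizationReport(obs, null_stats, float(p))
        return self.randomization_


def scan(dates: pd.DataFrame, weather: WeatherSeries, variable: str = "tmax",
         **settings) -> ClimateWindowScanner:
    """Functional wrapper over :class:`ClimateWindowScanner`."""
    return ClimateWindowScanner(variable=variable, **settings).fit(dates, weather)


def weight_surface(results: list[WindowResult]) -> pd.DataFrame:
    """Akaike-weight surface keyed by (open, close) for rendering."""
    return pd.DataFrame({
        "open_day": [r.window.open for r in results],
        "close_day": [r.window.close for r in results],
        "weight": [r.weight for r in results],
    })
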