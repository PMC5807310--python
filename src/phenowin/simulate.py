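"""Synthetic weather, species truth and nest-observation generator.

The generator reproduces the statistical structure the downstream analysis
assumes, with known ground truth:

* a daily temperature series built from a seasonal sinusoid, i.i.d. normal
  calendar-year offsets and AR(1) day-to-day noise, plus exponential daily
  rainfall — emulating a single interior-plateau weather station;
* species whose latent clutch-initiation dates are linear in the mean daily
  maximum temperature over a fixed calendar window (the "critical temperature
  period"), plus a year-level random effect and individual residual noise;
* an observation process that forward-simulates laying, incubation and the
  nestling period, discovers the nest at some stage, visits it every few
  days, and records the true initiation date only for a fraction of nests.

Default noise magnitudes are anchored to published coefficient and variance
shares for an interior British Columbia cavity-nester community (slope about
-2.25 d/degC with marginal R2 ~0.18 and conditional R2 ~0.31), which implies
a year-effect SD near 3 d and a residual SD near 6.5 d when the annual
window-mean maximum temperature varies with SD ~1.5 degC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .daycal import DAYS_PER_YEAR, format_day, resolve_day

NEST_COLUMNS = [
    "nest_id", "species", "year", "cavity_id",
    "first_activity_date", "first_activity_stage",
    "last_active_date", "outcome", "n_visits", "clutch_size",
    "observed_initiation", "is_known_second_attempt", "occupancy_order",
]

OUTCOMES = ("fledged", "failed_pre_hatch", "failed_pre_fledge", "unknown")


@dataclass
class WeatherParams:
    """Daily climate generator parameters (temperatures degC, rain mm/day)."""

    mean_temp: float = 4.5
    seasonal_amplitude: float = 12.0
    seasonal_phase: float = 200.0      # day-of-year of the seasonal peak
    year_sd: float = 0.8               # SD of i.i.d. calendar-year offsets
    ar1_rho: float = 0.65              # day-to-day noise autocorrelation
    noise_sd: float = 2.5              # AR(1) innovation SD
    tmin_offset: float = -6.0
    tmax_offset: float = 6.0
    rain_rate: float = 1.2             # mean daily rainfall

    def __post_init__(self):
        if self.seasonal_amplitude < 0:
            raise ValueError("seasonal_amplitude must be >= 0")
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.tmax_offset <= self.tmin_offset:
            raise ValueError("tmax_offset must exceed tmin_offset")


@dataclass
class SpeciesTruth:
    """Ground-truth phenology and life history for one simulated species."""

    species_id: str
    true_window: tuple[int, int] = (68, 95)   # day indices, e.g. Mar 9-Apr 5
    true_slope: float = -2.25                 # days per degC of window-mean tmax
    true_intercept: float = 160.0             # day index at 0 degC
    year_sd: float = 3.0                      # SD of year random effect (days)
    resid_sd: float = 6.5                     # individual residual SD (days)
    mean_clutch: float = 6.0
    lay_rate: float = 1.0                     # eggs per day
    incubation: int = 13                      # clutch completion -> hatch (days)
    nestling_days: int = 20                   # hatch -> fledge (days)

    def __post_init__(self):
        lo, hi = self.true_window
        if hi < lo:
            raise ValueError("true_window close precedes open")
        if hi - lo + 1 < 10:
            raise ValueError("true_window must span at least 10 days")
        if self.resid_sd <= 0:
            raise ValueError("resid_sd must be > 0")
        if self.lay_rate <= 0:
            raise ValueError("lay_rate must be > 0")


@dataclass
class ObservationParams:
    """How the field crew finds, revisits and records simulated nests."""

    p_initiation_observed: float = 352.0 / 1628.0
    visit_interval: tuple[int, int] = (3, 5)
    p_found_at_nestling: float = 0.35
    outcome_probs: dict = field(default_factory=lambda: {
        "fledged": 0.6, "failed_pre_hatch": 0.12,
        "failed_pre_fledge": 0.18, "unknown": 0.10,
    })
    p_second_attempt: float = 0.02
    p_second_occupancy: float = 0.03

    def __post_init__(self):
        for name in ("p_initiation_observed", "p_found_at_nestling",
                     "p_second_attempt", "p_second_occupancy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        total = sum(self.outcome_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"outcome_probs must sum to 1, got {total}")
        if set(self.outcome_probs) - set(OUTCOMES):
            raise ValueError(f"unknown outcome labels: {set(self.outcome_probs) - set(OUTCOMES)}")


class WeatherSeries:
    """Daily weather indexed by (calendar year, day-of-year), non-leap."""

    VARIABLES = ("tmax", "tmin", "tmean", "rain")

    def __init__(self, frame: pd.DataFrame):
        required = {"year", "doy", *self.VARIABLES}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"weather table missing columns: {sorted(missing)}")
        frame = frame.sort_values(["year", "doy"]).reset_index(drop=True)
        self.frame = frame
        self._key = frame["year"].to_numpy() * DAYS_PER_YEAR + frame["doy"].to_numpy()
        if np.any(np.diff(self._key) == 0):
            raise ValueError("duplicate (year, doy) rows in weather table")
        self._values = {v: frame[v].to_numpy(dtype=float) for v in self.VARIABLES}

    def __len__(self) -> int:
        return len(self.frame)

    def _locate(self, years: np.ndarray, doys: np.ndarray) -> np.ndarray:
        keys = np.asarray(years) * DAYS_PER_YEAR + np.asarray(doys)
        idx = np.searchsorted(self._key, keys)
        ok = (idx < len(self._key)) & (self._key[np.minimum(idx, len(self._key) - 1)] == keys)
        if not np.all(ok):
            bad = [format_day(int(d), int(y)) for y, d in
                   zip(np.asarray(years)[~ok], np.asarray(doys)[~ok])]
            raise KeyError(f"weather series is missing {len(bad)} day(s): {bad[:10]}")
        return idx

    def window_mean(self, variable: str, open_day: int, close_day: int,
                    breeding_year: int) -> float:
        """Mean of ``variable`` over day indices open..close of a breeding year."""
        if variable not in self.VARIABLES:
            raise ValueError(f"unknown weather variable {variable!r}")
        days = np.arange(int(open_day), int(close_day) + 1)
        ys, ds = zip(*(resolve_day(int(d), breeding_year) for d in days))
        idx = self._locate(np.array(ys), np.array(ds))
        return float(self._values[variable][idx].mean())

    def daily_values(self, variable: str, open_day: int, close_day: int,
                     breeding_year: int) -> np.ndarray:
        days = np.arange(int(open_day), int(close_day) + 1)
        ys, ds = zip(*(resolve_day(int(d), breeding_year) for d in days))
        idx = self._locate(np.array(ys), np.array(ds))
        return self._values[variable][idx]

    def to_csv_frame(self) -> pd.DataFrame:
        out = self.frame.copy()
        out.insert(0, "date", [format_day(int(d), int(y))
                               for y, d in zip(out["year"], out["doy"])])
        return out[["date", "year", "doy", "tmax", "tmin", "tmean", "rain"]]


def simulate_weather(params: WeatherParams, years, seed: int) -> WeatherSeries:
    """Simulate a daily weather series covering the breeding seasons.

    The series spans day 1 of the calendar year before the first breeding
    year through day 365 of the last breeding year, so every November-June
    scan range (and mid-winter truth windows) is covered.
    """
    years = sorted(int(y) for y in np.atleast_1d(np.asarray(years)).ravel())
    if len(years) == 0:
        raise ValueError("at least one breeding year must be requested")
    rng = np.random.default_rng(seed)
    cal_years = np.arange(years[0] - 1, years[-1] + 1)
    n_days = len(cal_years) * DAYS_PER_YEAR

    doy_seq = np.tile(np.arange(1, DAYS_PER_YEAR + 1), len(cal_years))
    year_seq = np.repeat(cal_years, DAYS_PER_YEAR)

    seasonal = params.mean_temp + params.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy_seq - params.seasonal_phase) / DAYS_PER_YEAR)
    offsets = rng.normal(0.0, params.year_sd, size=len(cal_years)) if params.year_sd > 0 \
        else np.zeros(len(cal_years))
    year_offset = np.repeat(offsets, DAYS_PER_YEAR)

    innov = rng.normal(0.0, params.noise_sd, size=n_days)
    noise = np.empty(n_days)
    # stationary start so the marginal SD is noise_sd/sqrt(1-rho^2) throughout
    noise[0] = innov[0] / np.sqrt(1.0 - params.ar1_rho**2)
    rho = params.ar1_rho
    for t in range(1, n_days):
        noise[t] = rho * noise[t - 1] + innov[t]

    tmean = seasonal + year_offset + noise
    tmax = tmean + params.tmax_offset + rng.normal(0.0, 0.5, size=n_days)
    tmin = tmean + params.tmin_offset + rng.normal(0.0, 0.5, size=n_days)
    rain = rng.exponential(params.rain_rate, size=n_days) if params.rain_rate > 0 \
        else np.zeros(n_days)

    return WeatherSeries(pd.DataFrame({
        "year": year_seq, "doy": doy_seq,
        "tmax": tmax, "tmin": tmin, "tmean": tmean, "rain": rain,
    }))


def _stage_at(day: float, initiation: float, hatch: float) -> str:
    if day < initiation:
        return "pre-lay"
    if day < hatch:
        return "egg"
    return "nestling"


def simulate_nests(truth: SpeciesTruth, weather: WeatherSeries,
                   obs: ObservationParams, years, n_per_year: int,
                   seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate nest records for one species.

    Returns ``(records, truth_table)``: the observation table (one row per
    nesting attempt, columns :data:`NEST_COLUMNS`) and the latent truth table
    (latent initiation, clutch, hatch and fledge dates for every attempt).
    The observation process only hides latent dates, it never alters them.
    """
    years = sorted(int(y) for y in np.atleast_1d(np.asarray(years)).ravel())
    rng = np.random.default_rng(seed)
    open_day, close_day = truth.true_window

    rows, truth_rows = [], []
    nest_counter = 0
    for year in years:
        temp = weather.window_mean("tmax", open_day, close_day, year)
        year_effect = rng.normal(0.0, truth.year_sd) if truth.year_sd > 0 else 0.0
        for i in range(int(n_per_year)):
            resid = rng.normal(0.0, truth.resid_sd) if truth.resid_sd > 0 else 0.0
            latent = int(round(truth.true_intercept + truth.true_slope * temp
                               + year_effect + resid))
            clutch = max(1, int(round(rng.normal(truth.mean_clutch, 1.0))))
            lay_span = (clutch - 1) / truth.lay_rate
            hatch = latent + lay_span + truth.incubation
            fledge = hatch + truth.nestling_days

            outcome = rng.choice(list(obs.outcome_probs),
                                 p=list(obs.outcome_probs.values()))
            if outcome == "failed_pre_hatch":
                end = rng.uniform(latent, hatch)
            elif outcome == "failed_pre_fledge":
                end = rng.uniform(hatch, fledge)
            else:
                end = fledge

            if rng.random() < obs.p_found_at_nestling and end > hatch:
                found = rng.uniform(hatch, end)
            else:
                found = rng.uniform(latent - 6, max(latent - 6, min(hatch, end)))
            found = min(found, end)

            interval = rng.uniform(*obs.visit_interval)
            visit_days = np.arange(found, end + interval, interval)
            visit_days = visit_days[visit_days <= end]
            if len(visit_days) == 0:
                visit_days = np.array([found])
            first_day = int(np.floor(visit_days[0]))
            last_day = int(np.floor(visit_days[-1]))
            stage = _stage_at(visit_days[0], latent, hatch)

            observed = rng.random() < obs.p_initiation_observed
            nest_counter += 1
            nest_id = f"{truth.species_id}-{year}-{nest_counter:04d}"
            cavity_id = f"cav-{truth.species_id}-{year}-{i:03d}"
            rows.append({
                "nest_id": nest_id, "species": truth.species_id, "year": year,
                "cavity_id": cavity_id,
                "first_activity_date": first_day,
                "first_activity_stage": stage,
                "last_active_date": max(last_day, first_day),
                "outcome": outcome, "n_visits": int(len(visit_days)),
                "clutch_size": clutch,
                "observed_initiation": latent if observed else np.nan,
                "is_known_second_attempt": bool(rng.random() < obs.p_second_attempt),
                "occupancy_order": 2 if rng.random() < obs.p_second_occupancy else 1,
            })
            truth_rows.append({
                "nest_id": nest_id, "species": truth.species_id, "year": year,
                "latent_initiation": latent, "clutch_size": clutch,
                "hatch_date": hatch, "fledge_date": fledge,
                "window_tmax": temp, "year_effect": year_effect,
            })
    records = pd.DataFrame(rows, columns=NEST_COLUMNS)
    return records, pd.DataFrame(truth_rows)


def simulate_ecology(years, seed: int) -> pd.DataFrame:
    """Annual ecological covariates: a pulsed beetle food resource and
    slowly varying small/medium and large cavity counts."""
    years = sorted(int(y) for y in np.atleast_1d(np.asarray(years)).ravel())
    rng = np.random.default_rng(seed)
    t = np.arange(len(years), dtype=float)
    peak = len(years) / 2.0
    mpb = 25.0 * np.exp(-0.5 * ((t - peak) / 2.5) ** 2) + rng.exponential(1.0, len(years))
    small_med = 120 + 8.0 * t + rng.normal(0, 10, len(years))
    large = 40 + 2.0 * t + rng.normal(0, 5, len(years))
    return pd.DataFrame({
        "year": years, "mpb_per_ha": mpb,
        "cavities_small_med": np.maximum(0, small_med).round(0),
        "cavities_large": np.maximum(0, large).round(0),
    })
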