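"""CSV readers/writers, input validation and run configuration."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .daycal import format_day, resolve_day
from .simulate import NEST_COLUMNS, OUTCOMES, WeatherSeries

STAGES = ("pre-lay", "egg", "nestling", "unknown")

LIFE_HISTORY_COLUMNS = [
    "species", "lay_rate", "mean_clutch", "incubation",
    "nesting_strategy", "mpb_consumer", "cavity_class",
]


@dataclass
class RunConfig:
    """Pipeline settings (defaults follow the published study protocol)."""

    seed: int = 0
    n_imputations: int = 100
    n_boot: int = 20
    n_imputations_annual: int = 500
    n_rand: int = 100
    range_start: int = -60            # Nov 1, previous year
    range_end: int = 152              # Jun 1
    min_width: int = 10
    step: int = 1
    variables: tuple = ("tmax", "tmin", "tmean", "rain")
    calendar: str = "noleap"
    nests: str = "nests.csv"
    weather: str = "weather.csv"
    ecology: str = "ecology.csv"
    life_history: str = "life_history.csv"
    outdir: str = "results"

    def __post_init__(self):
        for name in ("n_imputations", "n_boot", "n_imputations_annual", "n_rand"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "variables" in data:
            data["variables"] = tuple(data["variables"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def stage_seed(seed: int, label: str) -> int:
    """Stable per-stage substream seed: adding a stage never shifts another
    stage's draws (kept below 2**31)."""
    h = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_nests(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = set(NEST_COLUMNS) - {"nest_id"} - set(df.columns)
    if missing:
        raise ValueError(f"nest table missing columns: {sorted(missing)}")
    if "nest_id" not in df.columns:
        df.insert(0, "nest_id", [f"nest-{i:05d}" for i in range(len(df))])
    df["is_known_second_attempt"] = df["is_known_second_attempt"].astype(bool)
    return df


def read_weather(path) -> WeatherSeries:
    df = pd.read_csv(path, comment="#")
    if "year" not in df.columns or "doy" not in df.columns:
        if "date" not in df.columns:
            raise ValueError("weather table needs (year, doy) or date column")
        parsed = pd.to_datetime(df["date"])
        df["year"] = parsed.dt.year
        df["doy"] = parsed.dt.dayofyear
        # non-leap convention: drop Feb 29, shift later leap-year days back
        leap = parsed.dt.is_leap_year
        feb29 = leap & (parsed.dt.month == 2) & (parsed.dt.day == 29)
        df = df[~feb29].copy()
        late = leap[~feb29] & (df["doy"] > 60)
        df.loc[late, "doy"] -= 1
    return WeatherSeries(df)


def read_ecology(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if "year" not in df.columns:
        raise ValueError("ecology table must have a 'year' column")
    return df


def read_life_history(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = {"species", "lay_rate", "mean_clutch", "incubation"} - set(df.columns)
    if missing:
        raise ValueError(f"life-history table missing columns: {sorted(missing)}")
    return df.set_index("species", drop=False)


def write_table(df: pd.DataFrame, path, config: RunConfig | None = None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        if config is not None:
            fh.write(f"# phenowin config={config.config_hash()} seed={config.seed}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(nests: pd.DataFrame, weather: WeatherSeries,
                    ecology: pd.DataFrame | None,
                    life_history: pd.DataFrame,
                    range_start: int = -60, range_end: int = 152) -> ValidationReport:
    """Cross-check the four input tables before a run.

    Hard errors: weather gaps inside the scan range, date-order violations,
    duplicate (cavity, year, occupancy) keys, malformed stages/outcomes.
    Warnings: species without life-history entries (they are skipped).
    """
    rep = ValidationReport()

    bad_order = nests["last_active_date"] < nests["first_activity_date"]
    for _, r in nests[bad_order].iterrows():
        rep.errors.append(
            f"nest {r.get('nest_id', '?')}: last_active_date "
            f"{r['last_active_date']} precedes first_activity_date "
            f"{r['first_activity_date']}")

    dup = nests.duplicated(["cavity_id", "year", "occupancy_order"], keep=False)
    for key, grp in nests[dup].groupby(["cavity_id", "year", "occupancy_order"]):
        rep.errors.append(f"duplicate (cavity, year, occupancy) key: {key} "
                          f"({len(grp)} records)")

    bad_stage = ~nests["first_activity_stage"].isin(STAGES)
    if bad_stage.any():
        rep.errors.append(
            f"unknown stages: {sorted(nests.loc[bad_stage, 'first_activity_stage'].unique())}")
    bad_outcome = ~nests["outcome"].isin(OUTCOMES)
    if bad_outcome.any():
        rep.errors.append(
            f"unknown outcomes: {sorted(nests.loc[bad_outcome, 'outcome'].unique())}")

    obs = nests["observed_initiation"]
    egg_first = nests["first_activity_stage"].eq("egg")
    late_obs = obs.notna() & egg_first & (obs > nests["first_activity_date"])
    for _, r in nests[late_obs].iterrows():
        rep.errors.append(
            f"nest {r.get('nest_id', '?')}: observed initiation "
            f"{r['observed_initiation']} after first egg-stage activity "
            f"{r['first_activity_date']}")

    unknown_sp = set(nests["species"]) - set(life_history["species"])
    if unknown_sp:
        rep.warnings.append(
            f"species without life-history entries (skipped): {sorted(unknown_sp)}")

    # weather coverage of the scan range for every breeding year
    have = set(zip(weather.frame["year"].tolist(), weather.frame["doy"].tolist()))
    for year in sorted(nests["year"].unique()):
        missing = []
        for d in range(range_start, range_end + 1):
            yy, dd = resolve_day(d, int(year))
            if (yy, dd) not in have:
                missing.append(format_day(dd, yy))
        if missing:
            rep.errors.append(
                f"weather missing {len(missing)} day(s) in scan range of "
                f"breeding year {year}: {missing[:5]}"
                + ("..." if len(missing) > 5 else ""))

    if ecology is not None:
        missing_years = set(nests["year"].unique()) - set(ecology["year"])
        if missing_years:
            rep.warnings.append(
                f"ecology table missing years: {sorted(missing_years)}")
    return rep
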