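"""Candidate-model competition with imputation-bootstrap pooling.

Weather variables that survive the randomization guard and sit within
``dAICc <= 2`` of the best-performing variable are competed against a null
model (year random effect only), a linear temporal-trend model, models with
the annual ecological covariates appropriate to the species' guild (beetle
food pulse for beetle consumers; existing-cavity availability for secondary
cavity-nesters and facultative excavators), and additive weather+ecology
models.  Every candidate is refit over ``n_mi`` imputed datasets x ``n_boot``
within-year bootstrap resamples; reported coefficients are the medians and
the 2.5/97.5% quantiles of the pooled runs (no Rubin's rules), alongside the
variance-decomposition (marginal/conditional) R2 of the mixed model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import lmm
from .phenology import ImputedDataset
from .simulate import WeatherSeries
from .windows import WindowSpec, window_covariate

ECO_TERMS = ("mpb_per_ha", "cavities_small_med", "cavities_large")


@dataclass
class SpeciesTraits:
    """Guild attributes that decide which ecological models are plausible."""

    species_id: str
    nesting_strategy: str = "obligate"   # obligate | facultative | secondary
    mpb_consumer: bool = True
    cavity_class: str = "small_med"      # which cavity count is relevant

    @property
    def uses_existing_cavities(self) -> bool:
        return self.nesting_strategy in ("facultative", "secondary")

    @property
    def cavity_term(self) -> str:
        return ("cavities_large" if self.cavity_class == "large"
                else "cavities_small_med")


@dataclass
class CandidateModel:
    """One fixed-effect structure to compete (year random effect implicit)."""

    name: str
    terms: tuple = ()                 # column names in the year-level table
    window_refs: tuple = ()           # WindowSpec objects behind window terms


def build_candidate_set(traits: SpeciesTraits,
                        surviving: dict[str, "object"],
                        delta_aicc_max: float = 2.0) -> list[CandidateModel]:
    """Compose the candidate set from the surviving weather variables.

    ``surviving`` maps weather-variable name -> best WindowResult for the
    variables that passed the Type-I guard; variables more than
    ``delta_aicc_max`` AICc above the best variable are dropped here.  The
    null and temporal models are always present; guild-appropriate ecological
    and additive models are appended.
    """
    models = [CandidateModel("null"), CandidateModel("temporal", ("year_trend",))]

    weather_models = []
    if surviving:
        best = min(r.aicc for r in surviving.values())
        for var, res in sorted(surviving.items()):
            if res.aicc - best <= delta_aicc_max:
                weather_models.append(CandidateModel(
                    f"weather[{var}]", (f"window_{var}",), (res.window,)))
    models.extend(weather_models)

    eco_terms = []
    if traits.mpb_consumer:
        eco_terms.append("mpb_per_ha")
    if traits.uses_existing_cavities:
        eco_terms.append(traits.cavity_term)
    for term in eco_terms:
        models.append(CandidateModel(f"eco[{term}]", (term,)))
        for wm in weather_models:
            models.append(CandidateModel(
                f"{wm.name}+{term}", wm.terms + (term,), wm.window_refs))
    return models


def year_covariate_table(years, weather: WeatherSeries | None = None,
                         windows: dict[str, WindowSpec] | None = None,
                         ecology: pd.DataFrame | None = None) -> pd.DataFrame:
    """Year-level design columns: window means, centred year trend, ecology."""
    years = np.asarray(sorted(int(y) for y in years))
    tab = pd.DataFrame({"year": years})
    tab["year_trend"] = years - years.mean()
    if windows:
        for name, w in windows.items():
            tab[f"window_{name}"] = [window_covariate(weather, w, int(y))
                                     for y in years]
    if ecology is not None:
        tab = tab.merge(ecology, on="year", how="left")
    return tab


@dataclass
class PooledFit:
    """Imputation-bootstrap ensemble of one candidate model."""

    model: CandidateModel
    draws: pd.DataFrame = field(repr=False)   # one row per run, one col per term
    median: pd.Series = None
    lower: pd.Series = None
    upper: pd.Series = None
    marginal_r2: float = np.nan
    conditional_r2: float = np.nan
    aicc_median: float = np.nan
    n_records: int = 0
    n_failed: int = 0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.median.index, "median": self.median.values,
            "lower": self.lower.values, "upper": self.upper.values,
        })


def mi_bootstrap_fit(model: CandidateModel, imputations: list[ImputedDataset],
                     species: str, year_covariates: pd.DataFrame,
                     n_boot: int = 20, seed: int = 0,
                     bootstrap: str = "years") -> PooledFit:
    """Fit one candidate over every imputation x bootstrap resample.

    ``bootstrap='years'`` (default) is a cluster bootstrap: breeding years
    are resampled with replacement and each sampled year's records enter as
    a distinct pseudo-year.  Because every fixed covariate here is constant
    within a year, the year level is where the sampling noise of a
    coefficient lives; resampling only records within years would leave the
    year means almost unchanged and understate the coefficient ranges.
    ``'stratified'`` resamples records with replacement within each year
    (narrower ranges reflecting within-year noise only); ``'none'`` is the
    identity resample (every run refits the imputed dataset as-is).  Runs
    that fail are dropped when they are <= 5% of the total, otherwise the
    pooling aborts.
    """
    if bootstrap not in ("years", "stratified", "none"):
        raise ValueError(f"unknown bootstrap mode {bootstrap!r}")
    rng = np.random.default_rng(seed)
    cov = year_covariates.set_index("year")
    names = ["intercept", *model.terms]

    rows, r2s, aiccs = [], [], []
    n_failed = n_total = 0
    for ds in imputations:
        sub = ds.records[ds.records["species"] == species]
        y_all = sub["initiation"].to_numpy(dtype=float)
        yr_all = sub["year"].to_numpy(dtype=int)
        order = np.argsort(yr_all, kind="stable")
        y_all, yr_all = y_all[order], yr_all[order]
        uyears, starts = np.unique(yr_all, return_index=True)
        bounds = np.append(starts, len(yr_all))
        missing = [t for t in model.terms if t not in cov.columns]
        if missing:
            raise KeyError(f"year covariates missing terms: {missing}")
        X = np.column_stack(
            [np.ones(len(uyears))]
            + [cov.loc[uyears, t].to_numpy(dtype=float) for t in model.terms])
        if np.isnan(X).any():
            raise ValueError(f"covariates undefined for some years of {model.name}")
        # AICc and R2 come from the un-resampled fit of each imputation:
        # bootstrap resamples (duplicated years) inflate apparent signal and
        # would bias information-criterion comparisons toward larger models.
        fit0 = lmm.fit_random_intercept(y_all, yr_all, X, names)
        aiccs.append(fit0.aicc)
        r2s.append(fit0.r2_nakagawa())
        for b in range(n_boot):
            n_total += 1
            Xb = X
            if bootstrap == "stratified":
                idx = np.concatenate([
                    rng.integers(lo, hi, size=hi - lo)
                    for lo, hi in zip(bounds[:-1], bounds[1:])])
                y, yr = y_all[idx], yr_all[idx]
            elif bootstrap == "years":
                picks = rng.integers(0, len(uyears), size=len(uyears))
                idx = np.concatenate([
                    np.arange(bounds[j], bounds[j + 1]) for j in picks])
                y = y_all[idx]
                # distinct pseudo-year label per sampled cluster
                yr = np.repeat(np.arange(len(picks)),
                               bounds[picks + 1] - bounds[picks])
                Xb = X[picks]
            else:
                rows.append(fit0.beta)
                continue
            try:
                fit = lmm.fit_random_intercept(y, yr, Xb, names)
            except (np.linalg.LinAlgError, ValueError):
                n_failed += 1
                continue
            rows.append(fit.beta)
    if n_total and n_failed / n_total > 0.05:
        raise RuntimeError(
            f"{n_failed}/{n_total} runs failed for model {model.name!r}")
    draws = pd.DataFrame(rows, columns=names)
    r2 = np.asarray(r2s)
    return PooledFit(
        model=model, draws=draws,
        median=draws.median(), lower=draws.quantile(0.025),
        upper=draws.quantile(0.975),
        marginal_r2=float(np.median(r2[:, 0])),
        conditional_r2=float(np.median(r2[:, 1])),
        aicc_median=float(np.median(aiccs)),
        n_records=int(len(y_all)), n_failed=n_failed,
    )


def compete(candidates: list[CandidateModel], imputations, species,
            year_covariates, n_boot: int = 20, seed: int = 0) -> pd.DataFrame:
    """Pool every candidate; rank by median AICc across the runs."""
    fits = {}
    for i, m in enumerate(candidates):
        fits[m.name] = mi_bootstrap_fit(
            m, imputations, species, year_covariates, n_boot=n_boot,
            seed=seed + i)
    tab = pd.DataFrame({
        "model": list(fits),
        "aicc_median": [f.aicc_median for f in fits.values()],
        "marginal_r2": [f.marginal_r2 for f in fits.values()],
        "conditional_r2": [f.conditional_r2 for f in fits.values()],
    }).sort_values("aicc_median").reset_index(drop=True)
    tab["delta_aicc"] = tab["aicc_median"] - tab["aicc_median"].iloc[0]
    tab.attrs["fits"] = fits
    return tab


def r2_nakagawa(fit: lmm.RandomInterceptFit) -> tuple[float, float]:
    """Variance-decomposition R2 of a mixed fit.

    marginal = s2_f / (s2_f + s2_year + s2_resid);
    conditional = (s2_f + s2_year) / (s2_f + s2_year + s2_resid),
    with s2_f the variance of the fixed-effect linear predictor over records.
    """
    return fit.r2_nakagawa()


def annual_r2(pooled: PooledFit, annual_observed: pd.DataFrame,
              year_covariates: pd.DataFrame) -> float:
    """Squared Pearson correlation between model-predicted (median
    coefficients applied to the annual covariates) and observed annual mean
    initiation dates."""
    obs = annual_observed[annual_observed["multiple_nests"]]
    if len(obs) < 3:
        raise ValueError("need >= 3 years with multiple nests")
    cov = year_covariates.set_index("year")
    years = obs["year"].to_numpy(dtype=int)
    X = np.column_stack(
        [np.ones(len(years))]
        + [cov.loc[years, t].to_numpy(dtype=float) for t in pooled.model.terms])
    pred = X @ pooled.median.to_numpy()
    if np.std(pred) == 0:
        raise ValueError("constant predictions; annual R2 undefined")
    r = np.corrcoef(pred, obs["mean"].to_numpy(dtype=float))[0, 1]
    return float(r**2)
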