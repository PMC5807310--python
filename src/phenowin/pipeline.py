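"""End-to-end orchestration: impute -> scan -> guard -> compete -> synchrony.

Each stage draws from a stage-labelled RNG substream derived from the single
run seed, so adding or re-running one stage never shifts another stage's
draws and the full run is deterministic given (inputs, seed).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import competition, phenology, synchrony, windows
from .io import (RunConfig, read_ecology, read_life_history, read_nests,
                 read_weather, stage_seed, validate_inputs, write_table)
from .report import critical_period_summary

log = logging.getLogger("phenowin")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis from the four input CSVs.

    Writes per-species window results and weight surfaces, the pooled
    competition table, annual means, the synchrony matrix, the critical
    period report, and a machine-readable manifest.  Returns the artifact
    bundle as a dict of DataFrames.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    nests = read_nests(config.nests)
    weather = read_weather(config.weather)
    ecology = read_ecology(config.ecology) if Path(config.ecology).exists() else None
    life_history = read_life_history(config.life_history)

    report = validate_inputs(nests, weather, ecology, life_history,
                             config.range_start, config.range_end)
    for w in report.warnings:
        log.warning("validate: %s", w)
    if not report.ok:
        raise RuntimeError("input validation failed:\n" + "\n".join(report.errors))

    # ---- phenology stage -------------------------------------------------
    nests = phenology.backdate_nestlings(
        nests[nests["species"].isin(life_history["species"])], life_history)
    nests = phenology.filter_first_attempts(nests)
    model = phenology.InitiationModel().fit(nests)
    cv = phenology.cross_validate(nests, seed=stage_seed(config.seed, "cv"))
    log.info("cross-validation: mean r = %.3f, RMSPE = %.2f d", cv.mean_r, cv.rmspe)

    imputations = phenology.impute_datasets(
        nests, model, cv.rmspe, config.n_imputations,
        stage_seed(config.seed, "impute"))
    imputations_annual = phenology.impute_datasets(
        nests, model, cv.rmspe, config.n_imputations_annual,
        stage_seed(config.seed, "impute-annual"))

    species_list = sorted(nests["species"].unique())
    annual = pd.concat(
        [phenology.annual_means(imputations_annual, sp) for sp in species_list],
        ignore_index=True)

    # ---- window scan + Type-I guard + competition, per species -----------
    competition_rows, interval_rows, bundle_scans = [], [], {}
    for sp in species_list:
        sp_dates = imputations[0].records.query("species == @sp")
        surviving, best_windows = {}, {}
        for variable in config.variables:
            try:
                scanner = windows.ClimateWindowScanner(
                    variable=variable, range_start=config.range_start,
                    range_end=config.range_end, min_width=config.min_width,
                    step=config.step).fit(sp_dates, weather)
            except ValueError as exc:
                log.warning("%s/%s: scan skipped (%s)", sp, variable, exc)
                continue
            rand = scanner.randomization_test(
                config.n_rand, stage_seed(config.seed, f"rand:{sp}:{variable}"))
            bundle_scans[(sp, variable)] = scanner
            write_table(windows.weight_surface(scanner.results_),
                        outdir / f"weights_{sp}_{variable}.csv", config)
            if not rand.spurious:
                surviving[variable] = scanner.best_
                best_windows[variable] = scanner.best_.window
            log.info("%s/%s: best %s (slope %.2f), p = %.3f%s",
                     sp, variable, scanner.best_.window.label(),
                     scanner.best_.slope, rand.p_value,
                     " [spurious]" if rand.spurious else "")

        traits = competition.SpeciesTraits(
            sp,
            nesting_strategy=str(life_history.loc[sp].get("nesting_strategy", "obligate")),
            mpb_consumer=bool(life_history.loc[sp].get("mpb_consumer", True)),
            cavity_class=str(life_history.loc[sp].get("cavity_class", "small_med")),
        )
        candidates = competition.build_candidate_set(traits, surviving)
        candidates = [m for m in candidates
                      if ecology is not None or
                      not any(t in competition.ECO_TERMS for t in m.terms)]
        year_cov = competition.year_covariate_table(
            sp_dates["year"].unique(), weather, best_windows, ecology)
        tab = competition.compete(
            candidates, imputations, sp, year_cov, n_boot=config.n_boot,
            seed=stage_seed(config.seed, f"boot:{sp}"))
        best_fit = tab.attrs["fits"][tab["model"].iloc[0]]
        for term, med in best_fit.median.items():
            competition_rows.append({
                "species": sp, "model": best_fit.model.name, "term": term,
                "median": med, "lower": best_fit.lower[term],
                "upper": best_fit.upper[term],
                "marginal_r2": best_fit.marginal_r2,
                "conditional_r2": best_fit.conditional_r2,
                "n": best_fit.n_records,
            })

        sp_annual = annual.query("species == @sp and multiple_nests")
        if len(sp_annual) and "tmax" in best_windows:
            interval_rows.append(critical_period_summary(
                sp, best_windows["tmax"],
                round(sp_annual["mean"].mean())).as_row())

    results_table = pd.DataFrame(competition_rows)
    intervals = pd.DataFrame(interval_rows)
    sync = synchrony.pairwise_correlations(annual)

    write_table(annual, outdir / "annual_means.csv", config)
    write_table(results_table, outdir / "model_competition.csv", config)
    write_table(sync, outdir / "synchrony.csv", config)
    if len(intervals):
        write_table(intervals, outdir / "critical_periods.csv", config)

    manifest = {
        "seed": config.seed, "config_hash": config.config_hash(),
        "n_nests": int(len(nests)), "rmspe": cv.rmspe, "cv_mean_r": cv.mean_r,
        "species": species_list,
        "outputs": sorted(p.name for p in outdir.glob("*.csv")),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "nests": nests, "annual": annual, "competition": results_table,
        "synchrony": sync, "intervals": intervals, "cv": cv,
        "scans": bundle_scans, "manifest": manifest,
    }
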