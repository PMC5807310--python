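import warnings

import numpy as np
import pandas as pd
import pytest

import phenowin as pw

YEARS = list(range(1995, 2012))


@pytest.fixture(scope="session")
def weather():
    return pw.simulate_weather(pw.WeatherParams(), YEARS, seed=11)


@pytest.fixture(scope="session")
def nuthatch_truth():
    # window Mar 9-Apr 5, slope -2.25 d/degC: the community's mid-spring responder
    return pw.SpeciesTruth("nuthatch", true_window=(68, 95), true_slope=-2.25,
                           true_intercept=160.0)


@pytest.fixture(scope="session")
def nuthatch_bundle(weather, nuthatch_truth):
    """(records, truth_table) for one species over the full study span."""
    return pw.simulate_nests(nuthatch_truth, weather, pw.ObservationParams(),
                             YEARS, 30, seed=21)


@pytest.fixture(scope="session")
def community(weather):
    """Three-species community with backdated, first-attempt-filtered records
    and a life-history table."""
    lh_rows, frames, truths = [], [], {}
    for i, sp in enumerate(["chickadee", "nuthatch", "woodpecker"]):
        truth = pw.SpeciesTruth(
            sp, true_window=(45 + 12 * i, 80 + 12 * i),
            true_slope=-2.0 - 0.3 * i, true_intercept=148.0 + 7 * i)
        nests, tt = pw.simulate_nests(truth, weather, pw.ObservationParams(),
                                      YEARS, 25, seed=31 + i)
        frames.append(nests)
        truths[sp] = (truth, tt)
        lh_rows.append({
            "species": sp, "lay_rate": truth.lay_rate,
            "mean_clutch": truth.mean_clutch, "incubation": truth.incubation,
            "nesting_strategy": ["obligate", "facultative", "secondary"][i],
            "mpb_consumer": i != 2, "cavity_class": "small_med",
        })
    records = pd.concat(frames, ignore_index=True)
    life_history = pd.DataFrame(lh_rows).set_index("species", drop=False)
    records = pw.phenology.backdate_nestlings(records, {
        sp: t for sp, (t, _) in truths.items()})
    records = pw.filter_first_attempts(records)
    return {"records": records, "truths": truths, "life_history": life_history}


@pytest.fixture(scope="session")
def fitted_model(community):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pw.InitiationModel().fit(community["records"])


@pytest.fixture(scope="session")
def imputations(community, fitted_model):
    return pw.impute_datasets(community["records"], fitted_model,
                              rmspe=3.4, n_draws=20, seed=41)
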