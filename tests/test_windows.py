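import numpy as np
import pandas as pd
import pytest

import phenowin as pw
from phenowin import lmm
from phenowin.simulate import WeatherSeries
from phenowin.windows import (ClimateWindowScanner, WindowResult, WindowSpec,
                              enumerate_windows, weight_surface,
                              window_covariate)


class TestEnumerateWindows:
    def test_eleven_day_range(self):
        wins = enumerate_windows(1, 11, min_width=10)
        assert {(w.open, w.close) for w in wins} == {(1, 10), (2, 11), (1, 11)}

    def test_minimal_range_single_window(self):
        wins = enumerate_windows(1, 10, min_width=10)
        assert len(wins) == 1 and wins[0].width == 10

    def test_full_scan_count_matches_formula(self):
        # Nov 1 (prev year) - Jun 1: L = 213 days, m = 10
        wins = enumerate_windows(-60, 152, min_width=10, step=1)
        L, m = 213, 10
        assert len(wins) == (L - m + 1) * (L - m + 2) // 2 == 20910

    @pytest.mark.parametrize("L,m", [(15, 3), (20, 10), (12, 12)])
    def test_count_matches_brute_force(self, L, m):
        wins = enumerate_windows(1, L, min_width=m)
        brute = {(o, c) for o in range(1, L + 1) for c in range(o, L + 1)
                 if c - o + 1 >= m}
        assert {(w.open, w.close) for w in wins} == brute

    def test_step_keeps_full_range_window(self):
        wins = enumerate_windows(1, 30, min_width=10, step=7)
        assert WindowSpec(1, 30) in wins

    def test_invalid_min_width_rejected(self):
        with pytest.raises(ValueError):
            enumerate_windows(1, 30, min_width=0)


def _toy_weather(values_by_yearday):
    rows = [{"year": y, "doy": d, "tmax": v, "tmin": v - 5, "tmean": v - 2,
             "rain": 0.0} for (y, d), v in values_by_yearday.items()]
    return WeatherSeries(pd.DataFrame(rows))


class TestWindowCovariate:
    def test_constant_series(self):
        w = _toy_weather({(2000, d): 3.0 for d in range(1, 100)})
        assert window_covariate(w, WindowSpec(10, 40), 2000) == 3.0

    def test_arithmetic_mean(self):
        w = _toy_weather({(2000, d): float(d) for d in range(1, 11)})
        assert window_covariate(w, WindowSpec(1, 10), 2000) == 5.5

    def test_window_straddling_new_year(self):
        vals = {(1999, 364): 10.0, (1999, 365): 20.0, (2000, 1): 30.0,
                (2000, 2): 40.0}
        w = _toy_weather(vals)
        # days -1..2 of breeding year 2000 resolve into both calendar years
        assert window_covariate(w, WindowSpec(-1, 2), 2000) == 25.0

    def test_missing_days_named(self):
        w = _toy_weather({(2000, d): 1.0 for d in range(1, 50) if d != 20})
        with pytest.raises(KeyError, match="2000-01-20"):
            window_covariate(w, WindowSpec(10, 30), 2000)


@pytest.fixture(scope="module")
def strong_signal(weather, nuthatch_truth):
    _, tt = pw.simulate_nests(nuthatch_truth, weather, pw.ObservationParams(),
                              list(range(1995, 2012)), 30, seed=51)
    return tt.rename(columns={"latent_initiation": "initiation"})[
        ["year", "initiation"]]


class TestScan:
    def test_recovers_true_window_and_sign(self, weather, strong_signal):
        sc = ClimateWindowScanner(range_start=32, range_end=121, step=3).fit(
            strong_signal, weather)
        assert sc.best_.window.jaccard(WindowSpec(68, 95)) >= 0.5
        assert sc.best_.slope < 0

    def test_weights_sum_to_one(self, weather, strong_signal):
        sc = ClimateWindowScanner(range_start=32, range_end=121, step=3).fit(
            strong_signal, weather)
        assert sc.weights_.sum() == pytest.approx(1.0, abs=1e-9)
        assert min(r.delta_aicc for r in sc.results_) == 0.0

    def test_single_candidate_window_weight_one(self, weather, strong_signal):
        sc = ClimateWindowScanner(range_start=68, range_end=77,
                                  min_width=10).fit(strong_signal, weather)
        assert len(sc.results_) == 1
        assert sc.results_[0].weight == pytest.approx(1.0)

    def test_null_truth_close_to_intercept_model(self, weather):
        rng = np.random.default_rng(52)
        dates = pd.DataFrame({
            "year": np.repeat(np.arange(1995, 2012), 20),
            "initiation": rng.normal(140, 7, 17 * 20)})
        sc = ClimateWindowScanner(range_start=32, range_end=121, step=5).fit(
            dates, weather)
        # best-window AICc cannot beat the intercept-only model by much
        assert sc.observed_stat_ < 10
        rep = sc.randomization_test(n_rand=30, seed=53)
        assert rep.spurious

    def test_too_few_years_rejected(self, weather):
        dates = pd.DataFrame({"year": [2000] * 5 + [2001] * 5,
                              "initiation": np.arange(10.0)})
        with pytest.raises(ValueError, match=">= 3 years"):
            ClimateWindowScanner().fit(dates, weather)

    def test_scan_matches_mixedlm_oracle(self, weather, strong_signal):
        """AICc of the best window agrees with an independent statsmodels
        MixedLM fit of the same model."""
        import statsmodels.api as sm

        sc = ClimateWindowScanner(range_start=32, range_end=121, step=5).fit(
            strong_signal, weather)
        b = sc.best_
        counts = strong_signal.groupby("year").size()
        sub = strong_signal[strong_signal["year"].isin(
            counts[counts >= 2].index)]
        x = sub["year"].map(lambda y: window_covariate(
            weather, b.window, int(y)))
        df = pd.DataFrame({"y": sub["initiation"].to_numpy(),
                           "x": x.to_numpy(), "g": sub["year"].to_numpy()})
        res = sm.MixedLM.from_formula("y ~ x", groups="g", data=df).fit(reml=False)
        k, n = 4, len(df)
        aicc_ref = -2 * res.llf + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert b.aicc == pytest.approx(aicc_ref, abs=0.01)
        assert b.slope == pytest.approx(res.fe_params["x"], rel=1e-3)


class TestRandomization:
    def test_p_value_extremes(self, weather, strong_signal):
        sc = ClimateWindowScanner(range_start=60, range_end=100, step=5).fit(
            strong_signal, weather)
        # synthetic extremes of the rank statistic at n_rand = 100
        sc_obs = sc.observed_stat_
        nulls_hi = np.full(100, sc_obs + 1.0)
        nulls_lo = np.full(100, sc_obs - 1.0)
        p_hi = (1 + np.sum(nulls_hi >= sc_obs)) / 101
        p_lo = (1 + np.sum(nulls_lo >= sc_obs)) / 101
        assert p_hi == pytest.approx(1.0)
        assert p_lo == pytest.approx(1 / 101)

    def test_strong_signal_usually_passes_guard(self, weather, nuthatch_truth):
        """A -2.25 d/degC forcing is detected (p <= 0.05) in most replicate
        communities; the guard's power is high but not 1 at 17 years."""
        passed = 0
        for i in range(8):
            _, tt = pw.simulate_nests(
                nuthatch_truth, weather, pw.ObservationParams(),
                list(range(1995, 2012)), 30, seed=300 + i)
            dates = tt.rename(columns={"latent_initiation": "initiation"})[
                ["year", "initiation"]]
            sc = ClimateWindowScanner(range_start=32, range_end=121,
                                      step=3).fit(dates, weather)
            rep = sc.randomization_test(n_rand=50, seed=400 + i)
            assert len(rep.null_stats) == 50
            passed += rep.p_value <= 0.05
        assert passed >= 6

    def test_small_n_rand_warns(self, weather, strong_signal):
        sc = ClimateWindowScanner(range_start=60, range_end=100, step=5).fit(
            strong_signal, weather)
        with pytest.warns(UserWarning, match="unstable"):
            sc.randomization_test(n_rand=5, seed=55)


class TestWeightSurface:
    def _results(self, aiccs):
        wins = [WindowSpec(i, i + 10) for i in range(len(aiccs))]
        weights = lmm.akaike_weights(aiccs)
        best = min(aiccs)
        return [WindowResult(w, a, a - best, wgt, 0.0, 100)
                for w, a, wgt in zip(wins, aiccs, weights)]

    def test_uniform_on_equal_aicc(self):
        surf = weight_surface(self._results([10.0] * 5))
        assert np.allclose(surf["weight"], 0.2)

    def test_dominant_window(self):
        surf = weight_surface(self._results([100.0] + [120.0] * 9))
        assert surf["weight"].iloc[0] > 0.99

    def test_surface_conserves_mass(self, weather, strong_signal):
        sc = ClimateWindowScanner(range_start=60, range_end=100, step=4).fit(
            strong_signal, weather)
        surf = weight_surface(sc.results_)
        assert surf["weight"].sum() == pytest.approx(1.0, abs=1e-9)
        assert surf.groupby("close_day")["weight"].sum().sum() == pytest.approx(1.0, abs=1e-9)
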