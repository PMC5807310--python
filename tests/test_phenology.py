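import warnings

import numpy as np
import pandas as pd
import pytest

import phenowin as pw
from phenowin.phenology import (CvReport, InitiationModel,
                                backdate_nestling_record, cross_validate,
                                filter_first_attempts, impute_datasets,
                                annual_means)


def _record(**kw):
    base = {
        "nest_id": "n1", "species": "sp", "year": 2000, "cavity_id": "c1",
        "first_activity_date": 100, "first_activity_stage": "nestling",
        "last_active_date": 120, "outcome": "fledged", "n_visits": 4,
        "clutch_size": np.nan, "observed_initiation": np.nan,
        "is_known_second_attempt": False, "occupancy_order": 1,
    }
    base.update(kw)
    return pd.Series(base)


class TestBackdating:
    @pytest.mark.parametrize("clutch,lay_rate,incubation,hatch,expected", [
        (1, 1.0, 12, 100, 88),     # single egg: no laying-interval term
        (6, 1.0, 12, 100, 83),     # 5 laying days + 12 incubation days
        (5, 0.5, 10, 120, 102),    # 8 laying days + 10 incubation days
    ])
    def test_backdate_examples(self, clutch, lay_rate, incubation, hatch, expected):
        lh = {"sp": {"mean_clutch": 4.0, "lay_rate": lay_rate,
                     "incubation": incubation}}
        rec = _record(first_activity_date=hatch, clutch_size=clutch)
        out = backdate_nestling_record(rec, lh)
        assert out["first_activity_date"] == expected
        assert out["first_activity_stage"] == "egg"

    def test_forward_simulation_roundtrip(self):
        """Backdating inverts the simulator's lay -> incubation arithmetic."""
        truth = pw.SpeciesTruth("sp", mean_clutch=6, lay_rate=1.0, incubation=13)
        initiation, clutch = 130, 6
        hatch = initiation + (clutch - 1) / truth.lay_rate + truth.incubation
        rec = _record(first_activity_date=int(hatch), clutch_size=clutch)
        out = backdate_nestling_record(rec, {"sp": truth})
        assert out["first_activity_date"] == initiation

    def test_mean_clutch_used_when_missing(self):
        lh = {"sp": {"mean_clutch": 5.0, "lay_rate": 1.0, "incubation": 10}}
        out = backdate_nestling_record(_record(first_activity_date=100), lh)
        assert out["first_activity_date"] == 100 - 10 - 4

    def test_unknown_species_named_in_error(self):
        with pytest.raises(KeyError, match="nuthatch"):
            backdate_nestling_record(_record(species="nuthatch"), {})


class TestFirstAttemptFilter:
    def _toy(self):
        rows = [_record(nest_id=f"n{i}", cavity_id=f"c{i}") for i in range(6)]
        rows[1]["is_known_second_attempt"] = True
        rows[2]["occupancy_order"] = 2
        return pd.DataFrame(rows)

    def test_stated_rules_by_enumeration(self):
        out = filter_first_attempts(self._toy())
        assert len(out) == 4
        assert not out["is_known_second_attempt"].any()
        assert (out["occupancy_order"] == 1).all()

    def test_no_flags_unchanged(self):
        df = pd.DataFrame([_record(nest_id=f"n{i}") for i in range(4)])
        assert len(filter_first_attempts(df)) == 4

    def test_idempotent_and_monotone(self, community):
        once = filter_first_attempts(community["records"])
        twice = filter_first_attempts(once)
        pd.testing.assert_frame_equal(once, twice)
        assert len(once) <= len(community["records"])


class TestInitiationModel:
    def test_identity_mapping_recovered(self):
        """Nests found at pre-lay with initiation == first activity date:
        the date covariate should carry slope ~1 and the rest ~0."""
        rng = np.random.default_rng(0)
        n = 200
        dates = rng.integers(100, 160, n)
        df = pd.DataFrame([
            _record(nest_id=f"n{i}", species=["a", "b"][i % 2],
                    first_activity_date=int(d), first_activity_stage="pre-lay",
                    last_active_date=int(d) + int(rng.integers(20, 40)),
                    n_visits=int(rng.integers(2, 9)),
                    observed_initiation=int(d))
            for i, d in enumerate(dates)])
        m = InitiationModel().fit(df)
        coef = dict(zip(m.feature_names_, m.fe_params_))
        assert coef["first_activity_date"] == pytest.approx(1.0, abs=0.02)
        assert abs(coef["last_active_date"]) < 0.02
        assert np.allclose(m.predict(df), df["observed_initiation"], atol=0.5)

    def test_too_few_observed_rejected(self):
        df = pd.DataFrame([_record(nest_id=f"n{i}", observed_initiation=100)
                           for i in range(5)])
        with pytest.raises(ValueError, match=">= 20"):
            InitiationModel().fit(df)

    def test_single_species_falls_back_with_warning(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame([
            _record(nest_id=f"n{i}",
                    first_activity_date=int(d), first_activity_stage="egg",
                    observed_initiation=int(d) - 3)
            for i, d in enumerate(rng.integers(100, 160, 30))])
        with pytest.warns(UserWarning, match="single species"):
            m = InitiationModel().fit(df)
        assert not m.is_mixed_

    def test_unseen_species_uses_population_intercept(self, fitted_model,
                                                      community):
        rec = community["records"].iloc[[0]].copy()
        base = fitted_model.predict(rec)[0] - fitted_model.random_effects_.get(
            rec["species"].iloc[0], 0.0)
        rec["species"] = "martian_woodpecker"
        assert fitted_model.predict(rec)[0] == pytest.approx(base)

    def test_heldout_rmse_near_noise_floor(self, weather):
        """With injected N(0,2) prediction noise the held-out RMSE sits at
        the noise floor."""
        rng = np.random.default_rng(2)
        n = 500
        dates = rng.integers(100, 160, n)
        df = pd.DataFrame([
            _record(nest_id=f"n{i}", species=["a", "b"][i % 2],
                    first_activity_date=int(d), first_activity_stage="egg",
                    last_active_date=int(d) + int(rng.integers(20, 40)),
                    n_visits=int(rng.integers(2, 9)),
                    observed_initiation=float(d) - 4 + rng.normal(0, 2.0))
            for i, d in enumerate(dates)])
        cv = cross_validate(df, seed=3)
        assert 1.8 <= cv.rmspe <= 2.3


class TestCrossValidation:
    def test_fold_geometry_rejected(self):
        df = pd.DataFrame([_record(nest_id=f"n{i}", observed_initiation=100)
                           for i in range(30)])
        with pytest.raises(ValueError, match="disjoint"):
            cross_validate(df, k=6, test_fraction=0.2)

    def test_noiseless_data_perfect(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame([
            _record(nest_id=f"n{i}", species=["a", "b"][i % 2],
                    first_activity_date=int(d), first_activity_stage="pre-lay",
                    last_active_date=int(d) + int(rng.integers(20, 40)),
                    n_visits=int(rng.integers(2, 9)),
                    observed_initiation=int(d))
            for i, d in enumerate(rng.integers(100, 160, 200))])
        cv = cross_validate(df, seed=5)
        assert cv.mean_r > 0.999
        assert cv.rmspe < 0.1

    def test_shuffled_responses_uninformative(self):
        rng = np.random.default_rng(6)
        n = 350
        df = pd.DataFrame([
            _record(nest_id=f"n{i}", species=["a", "b"][i % 2],
                    first_activity_date=int(rng.integers(100, 160)),
                    last_active_date=int(rng.integers(160, 200)),
                    n_visits=int(rng.integers(2, 9)),
                    observed_initiation=float(rng.integers(100, 160)))
            for i in range(n)])
        cv = cross_validate(df, seed=7)
        assert abs(cv.mean_r) < 0.3


class TestImputation:
    def test_zero_rmspe_reproduces_point_predictions(self, community,
                                                     fitted_model):
        draws = impute_datasets(community["records"], fitted_model, 0.0, 3,
                                seed=8)
        for d in draws[1:]:
            pd.testing.assert_frame_equal(draws[0].records, d.records)

    def test_observed_dates_identical_across_draws(self, imputations,
                                                   community):
        obs_mask = community["records"]["observed_initiation"].notna().to_numpy()
        ref = imputations[0].records.loc[obs_mask, "initiation"]
        for d in imputations[1:]:
            assert (d.records.loc[obs_mask, "initiation"] == ref).all()
        assert not d.records.loc[obs_mask, "imputed"].any()

    def test_imputation_noise_has_configured_sd(self, community, fitted_model):
        rmspe = 3.4
        draws = impute_datasets(community["records"], fitted_model, rmspe,
                                300, seed=9)
        mat = np.stack([d.records["initiation"].to_numpy() for d in draws])
        imputed = draws[0].records["imputed"].to_numpy()
        per_record_sd = mat[:, imputed].std(axis=0, ddof=1)
        assert 0.9 * rmspe < per_record_sd.mean() < 1.1 * rmspe

    def test_negative_rmspe_rejected(self, community, fitted_model):
        with pytest.raises(ValueError):
            impute_datasets(community["records"], fitted_model, -1.0, 1, seed=0)


class TestAnnualMeans:
    def _toy_imputations(self, dates_by_year, n_draws=5, jitter=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = [{"nest_id": f"n{y}-{i}", "species": "sp", "year": y,
                 "initiation": float(d), "imputed": jitter > 0}
                for y, ds in dates_by_year.items() for i, d in enumerate(ds)]
        base = pd.DataFrame(rows)
        out = []
        for k in range(n_draws):
            df = base.copy()
            if jitter:
                df["initiation"] += rng.normal(0, jitter, len(df))
            out.append(pw.phenology.ImputedDataset(k, df))
        return out

    def test_constant_year_zero_width_ci(self):
        ann = annual_means(self._toy_imputations({2000: [140, 140, 140]}), "sp")
        row = ann.iloc[0]
        assert row["mean"] == 140
        assert row["ci_lo"] == row["ci_hi"] == 140

    def test_noiseless_matches_direct_mean(self):
        ann = annual_means(self._toy_imputations({2000: [140, 150]}), "sp")
        assert ann["mean"].iloc[0] == 145

    def test_zero_mean_noise_unbiased(self):
        imps = self._toy_imputations({2000: [140, 150, 160]}, n_draws=500,
                                     jitter=3.4, seed=1)
        ann = annual_means(imps, "sp")
        assert ann["mean"].iloc[0] == pytest.approx(150, abs=0.3)

    def test_single_nest_year_flagged(self):
        ann = annual_means(
            self._toy_imputations({2000: [140, 150], 2001: [145]}), "sp")
        assert ann.set_index("year")["multiple_nests"].to_dict() == {
            2000: True, 2001: False}

    def test_absent_species_empty_not_error(self, imputations):
        assert len(annual_means(imputations, "dodo")) == 0
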