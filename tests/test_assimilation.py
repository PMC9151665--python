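"""Within-season Powell calibration: objective, recovery, hybrid, cross-region."""

import numpy as np
import pandas as pd
import pytest

from ricelai import (
    DEFAULT_BOUNDS,
    CropParameters,
    LAIAssimilation,
    ObservationSet,
    RegressorSpec,
    cross_region_evaluate,
    powell_calibrate,
    run_hybrid,
    simulate_lai,
    train,
)
from ricelai.exceptions import InsufficientDataError, InvalidInputError
from ricelai.ml import FitResult
from ricelai.synthetic import dataset_to_feature_table


@pytest.fixture
def truth_setup(small_region):
    ps = small_region.pixel_seasons[0]
    comp_dates = ps.season.dates[8::8]
    obs = ObservationSet(dates=comp_dates, lai_obs=ps.true_lai.at(comp_dates))
    return ps, obs


class TestObjective:
    def test_self_consistency_is_zero(self, truth_setup):
        ps, obs = truth_setup
        model = LAIAssimilation(obs, ps.weather, ps.season)
        assert model.objective(ps.true_params) == pytest.approx(0.0, abs=1e-20)

    def test_single_half_unit_residual(self, truth_setup):
        ps, obs = truth_setup
        shifted = obs.lai_obs.copy()
        shifted[2] += 0.5  # one obs off by 0.5 -> SSE 0.25
        model = LAIAssimilation(
            ObservationSet(obs.dates, shifted), ps.weather, ps.season
        )
        assert model.objective(ps.true_params) == pytest.approx(0.25)

    def test_matches_loop_summation_oracle(self, truth_setup):
        ps, obs = truth_setup
        rng = np.random.default_rng(5)
        noisy = np.maximum(0, obs.lai_obs + rng.normal(0, 0.3, len(obs)))
        model = LAIAssimilation(ObservationSet(obs.dates, noisy), ps.weather, ps.season)
        p = CropParameters(l0=0.2, a=0.009, b=3.0, c=1.5e-3)
        traj = simulate_lai(p, ps.weather, ps.season)
        lai_by_date = dict(zip(traj.dates, traj.lai))
        expected = 0.0
        for d, o in zip(obs.dates, noisy):
            expected += (lai_by_date[d] - o) ** 2
        assert model.objective(p) == pytest.approx(expected, rel=1e-12)

    def test_obs_outside_span_rejected(self, truth_setup):
        ps, obs = truth_setup
        bad_dates = obs.dates.union([obs.dates[-1] + pd.Timedelta(days=800)])
        with pytest.raises(InvalidInputError):
            LAIAssimilation(
                ObservationSet(bad_dates, np.ones(len(bad_dates))),
                ps.weather,
                ps.season,
            )

    def test_fewer_than_four_observations_rejected(self, truth_setup):
        ps, obs = truth_setup
        with pytest.raises(InsufficientDataError):
            ObservationSet(obs.dates[:3], obs.lai_obs[:3])


class TestPowell:
    def test_start_at_truth_stays_at_truth(self, truth_setup):
        ps, obs = truth_setup
        res = powell_calibrate(obs, ps.weather, ps.season, init=ps.true_params)
        assert res.objective == pytest.approx(0.0, abs=1e-10)
        for n in CropParameters.names:
            assert getattr(res.params, n) == pytest.approx(getattr(ps.true_params, n), rel=0.01)

    def test_recovery_from_perturbed_start(self, truth_setup):
        ps, obs = truth_setup
        tv = ps.true_params.as_array()
        start = CropParameters.from_array(tv * 1.2)
        res = powell_calibrate(obs, ps.weather, ps.season, init=start)
        assert res.objective < 1e-6
        rel = np.abs(res.params.as_array() - tv) / tv
        assert np.all(rel < 0.05)

    def test_params_within_bounds_and_monotone_improvement(self, truth_setup):
        ps, obs = truth_setup
        rng = np.random.default_rng(8)
        noisy = np.maximum(0, obs.lai_obs + rng.normal(0, 0.3, len(obs)))
        res = powell_calibrate(
            ObservationSet(obs.dates, noisy), ps.weather, ps.season
        )
        assert DEFAULT_BOUNDS.contains(res.params)
        assert res.objective <= res.start_objective

    def test_slice_fit_respects_fixed_parameters(self, truth_setup):
        ps, obs = truth_setup
        tp = ps.true_params
        res = LAIAssimilation(obs, ps.weather, ps.season).fit(
            fixed={"l0": tp.l0, "c": tp.c}
        )
        assert res.params.l0 == tp.l0 and res.params.c == tp.c
        assert res.params.a == pytest.approx(tp.a, rel=0.01)
        assert res.params.b == pytest.approx(tp.b, rel=0.01)

    def test_summary_and_result_dict(self, truth_setup):
        ps, obs = truth_setup
        res = powell_calibrate(obs, ps.weather, ps.season, init=ps.true_params)
        text = res.summary()
        assert "Powell" in text and "RMSE" in text
        d = res.to_dict()
        assert set(d["params"]) == set(CropParameters.names)
        assert d["objective"] >= 0 and isinstance(d["converged"], bool)


class TestHybrid:
    def test_memorizing_regressor_closes_the_loop(self, clean_region):
        table = dataset_to_feature_table(clean_region, use_true_lai=True)
        fit = train(RegressorSpec("extra_trees", seed=0), table, profile="test")
        ps = clean_region.pixel_seasons[0]
        res = run_hybrid(ps.weather, fit, ps.season)
        rmse_traj = float(np.sqrt(np.mean((res.trajectory.lai - ps.true_lai.lai) ** 2)))
        assert rmse_traj < 0.05
        assert res.model.obs.source == "ml_estimated"

    def test_constant_regressor_is_handled_robustly(self, small_region):
        class ConstantModel:
            def predict(self, X):
                return np.full(len(X), 2.0)

        fit = FitResult(
            spec=RegressorSpec("ridge"), model=ConstantModel(), train_score=0.0
        )
        ps = small_region.pixel_seasons[0]
        res = run_hybrid(ps.weather, fit, ps.season)
        assert np.isfinite(res.objective)
        assert DEFAULT_BOUNDS.contains(res.params)

    def test_too_few_composite_dates_rejected(self, small_region):
        class ConstantModel:
            def predict(self, X):
                return np.full(len(X), 2.0)

        fit = FitResult(
            spec=RegressorSpec("ridge"), model=ConstantModel(), train_score=0.0
        )
        ps = small_region.pixel_seasons[0]
        with pytest.raises(InsufficientDataError):
            run_hybrid(ps.weather, fit, ps.season, composite_dates=ps.season.dates[8:25:8])


class TestCrossRegion:
    def test_single_region_diagonal_table(self, small_region):
        table = dataset_to_feature_table(small_region)
        fit = train(RegressorSpec("random_forest", seed=0), table, profile="test")
        out = cross_region_evaluate({"r1": fit}, {"r1": table})
        assert set(out["model_region"]) == {"r1"} and set(out["region"]) == {"r1"}
        assert len(out) == table["year"].nunique()
        assert np.isfinite(out[["rmse", "me"]].to_numpy()).all()
        assert ((out["me"] > 0) & (out["me"] <= 1)).all()

    def test_shifted_climatology_degrades_transfer(self):
        # a regressor trained on a cooler region loses skill on a warmer one
        from ricelai import RegionGeneratorConfig, gen_region

        cool = gen_region(RegionGeneratorConfig(
            name="cool", n_pixels=10, years=(2014, 2015), seed=31, temp_mean=11.0))
        warm = gen_region(RegionGeneratorConfig(
            name="warm", n_pixels=10, years=(2014, 2015), seed=32, temp_mean=15.5))
        t_cool = dataset_to_feature_table(cool)
        t_warm = dataset_to_feature_table(warm)
        fit = train(RegressorSpec("random_forest", seed=31), t_cool, profile="test")
        out = cross_region_evaluate({"cool": fit}, {"cool": t_cool, "warm": t_warm})
        within = out[out["region"] == "cool"]["me"].mean()
        cross = out[out["region"] == "warm"]["me"].mean()
        assert cross <= within
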