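"""Regressor stage: feature building, splitting, training, grid search, prediction."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from ricelai import (
    RegressorSpec,
    SeasonConfig,
    build_features,
    grid_search_alpha,
    predict_lai,
    split_train_test,
    train,
)
from ricelai.exceptions import (
    ConfigError,
    InsufficientDataError,
    InvalidInputError,
    UndefinedStatisticError,
)
from ricelai.ml import FAMILIES, evaluate


def _table(n, seed=0, target="linear"):
    rng = np.random.default_rng(seed)
    t = pd.DataFrame(
        {
            "cum_srad": rng.uniform(100, 2500, n),
            "cum_tmax": rng.uniform(200, 3800, n),
            "cum_tmin": rng.uniform(100, 2800, n),
        }
    )
    if target == "linear":
        t["lai"] = 0.001 * t.cum_srad + 0.0005 * t.cum_tmax - 0.0002 * t.cum_tmin + 0.3
    elif target == "noise":
        t["lai"] = rng.normal(size=n)
    elif target == "smooth":
        t["lai"] = 3.0 * np.sin(t.cum_srad / 800) * np.exp(-((t.cum_tmax - 2000) / 1500) ** 2)
    return t


class TestBuildFeatures:
    season = SeasonConfig(transplant_date=date(2014, 5, 17))

    def _weather(self):
        return pd.DataFrame(
            {
                "date": pd.date_range("2014-05-17", periods=60, freq="D"),
                "tmax": 30.0,
                "tmin": 20.0,
                "srad": 20.0,
            }
        )

    def test_constant_weather_accumulations(self):
        obs = pd.DataFrame(
            {"pixel_id": "p", "date": [pd.Timestamp("2014-05-25")], "lai": [1.0]}
        )
        t = build_features({"p": self._weather()}, obs, self.season)
        row = t.iloc[0]
        assert row.cum_srad == 160.0    # 8 days x 20
        assert row.cum_tmax == 240.0    # 8 days x 30
        assert row.cum_tmin == 160.0

    def test_row_count_and_pre_transplant_skip(self):
        dates = pd.date_range("2014-05-25", periods=5, freq="8D")
        obs = pd.concat(
            [
                pd.DataFrame({"pixel_id": p, "date": dates, "lai": 1.0})
                for p in ("p1", "p2")
            ]
        )
        early = pd.DataFrame(
            {"pixel_id": ["p1"], "date": [pd.Timestamp("2014-05-10")], "lai": [1.0]}
        )
        obs = pd.concat([obs, early])
        w = self._weather()
        t = build_features({"p1": w, "p2": w}, obs, self.season)
        assert len(t) == 2 * 5  # early sample skipped
        grp = t.groupby("pixel_id")["cum_srad"]
        assert (grp.apply(lambda s: np.all(np.diff(s) > 0))).all()  # non-decreasing


class TestSplit:
    def test_sizes_and_partition(self):
        t = _table(10)
        tr, te = split_train_test(t, 0.8, seed=1)
        assert (len(tr), len(te)) == (8, 2)
        merged = pd.concat([tr, te]).sort_values("cum_srad").reset_index(drop=True)
        orig = t.sort_values("cum_srad").reset_index(drop=True)
        pd.testing.assert_frame_equal(merged, orig)

    def test_seed_determinism(self):
        t = _table(50)
        a = split_train_test(t, 0.8, seed=3)
        b = split_train_test(t, 0.8, seed=3)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_too_few_rows(self):
        with pytest.raises(InsufficientDataError):
            split_train_test(_table(4), 0.8, seed=0)


class TestTrain:
    def test_linear_target_perfect_fit(self):
        t = _table(200)
        fit = train(RegressorSpec("polynomial_linear", {"degree": 1}), t)
        assert fit.train_score == pytest.approx(1.0, abs=1e-9)

    def test_pure_noise_scores_near_zero(self):
        t = _table(5000, seed=5, target="noise")
        tr, te = split_train_test(t, 0.8, seed=5)
        fit = train(RegressorSpec("ridge"), tr, te)
        assert abs(fit.test_score) < 0.1

    def test_random_forest_learns_smooth_nonlinear_target(self):
        t = _table(5000, seed=6, target="smooth")
        tr, te = split_train_test(t, 0.8, seed=6)
        fit = train(RegressorSpec("random_forest", seed=6), tr, te, profile="test")
        assert fit.test_score > 0.9

    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigError):
            RegressorSpec("perceptron")

    def test_zero_variance_target_rejected(self):
        t = _table(50)
        t["lai"] = 2.0
        with pytest.raises(UndefinedStatisticError):
            train(RegressorSpec("ridge"), t)

    def test_seeded_families_reproducible(self):
        t = _table(400, seed=2, target="smooth")
        tr, te = split_train_test(t, 0.8, seed=2)
        for fam in ("random_forest", "xgb"):
            s1 = train(RegressorSpec(fam, seed=11), tr, te, profile="test")
            s2 = train(RegressorSpec(fam, seed=11), tr, te, profile="test")
            assert (s1.train_score, s1.test_score) == (s2.train_score, s2.test_score)

    def test_scores_never_exceed_one(self):
        t = _table(300, seed=8, target="smooth")
        tr, te = split_train_test(t, 0.8, seed=8)
        for fam in FAMILIES:
            if fam == "dnn":
                continue
            fit = train(RegressorSpec(fam, seed=1), tr, te, profile="test")
            assert fit.train_score <= 1.0 and fit.test_score <= 1.0


class TestGridSearch:
    def test_singleton_grid(self):
        t = _table(100, seed=3)
        assert grid_search_alpha("ridge", [0.5], t, seed=3) == 0.5

    def test_matches_exhaustive_oracle(self):
        t = _table(300, seed=4, target="smooth")
        grid = [0.01, 0.1, 1.0]
        best = grid_search_alpha("ridge", grid, t, seed=4)
        tr, te = split_train_test(t, 0.8, seed=4)
        scores = {
            a: train(RegressorSpec("ridge", {"alpha": a}, 4), tr, te).test_score
            for a in grid
        }
        oracle = min(  # max score; ties to smallest alpha
            grid, key=lambda a: (-scores[a], a)
        )
        assert best == oracle

    def test_duplicate_alphas_tie_to_that_value(self):
        t = _table(100, seed=3)
        assert grid_search_alpha("lasso", [0.2, 0.2, 0.2], t, seed=3) == 0.2

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigError):
            grid_search_alpha("ridge", [], _table(100))


class TestPredict:
    def test_perfect_linear_model_reproduces_targets(self):
        t = _table(200)
        fit = train(RegressorSpec("polynomial_linear", {"degree": 1}), t)
        np.testing.assert_allclose(predict_lai(fit, t), t["lai"], rtol=1e-8)

    def test_negative_predictions_clipped_to_zero(self):
        t = _table(200)
        t["lai"] = -1.0 + 0.0001 * t["cum_srad"]  # mostly negative
        fit = train(RegressorSpec("polynomial_linear", {"degree": 1}), t)
        pred = predict_lai(fit, t)
        assert (pred >= 0).all() and (pred == 0).any()

    def test_forest_predictions_within_target_range(self):
        t = _table(2000, seed=9, target="smooth")
        fit = train(RegressorSpec("random_forest", seed=9), t, profile="test")
        rng = np.random.default_rng(10)
        new = pd.DataFrame(
            {
                "cum_srad": rng.uniform(0, 5000, 500),
                "cum_tmax": rng.uniform(0, 8000, 500),
                "cum_tmin": rng.uniform(0, 6000, 500),
            }
        )
        pred = predict_lai(fit, new)
        # tree ensembles average leaf values: cannot leave the training range
        assert pred.max() <= t["lai"].max() + 1e-9
        assert pred.min() >= max(0.0, t["lai"].min()) - 1e-9

    def test_schema_mismatch_rejected(self):
        t = _table(100)
        fit = train(RegressorSpec("ridge"), t)
        with pytest.raises(InvalidInputError):
            predict_lai(fit, t.drop(columns=["cum_tmin"]))

    def test_evaluate_matches_manual_r2(self):
        from ricelai import metrics

        t = _table(300, seed=12, target="smooth")
        tr, te = split_train_test(t, 0.8, seed=12)
        fit = train(RegressorSpec("hgb", seed=12), tr)
        manual = metrics.r2_score(
            te["lai"], fit.model.predict(te[["cum_srad", "cum_tmax", "cum_tmin"]])
        )
        assert evaluate(fit, te) == pytest.approx(manual)
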