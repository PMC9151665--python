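"""LAI estimation from climate factors with interchangeable regressors.

Features are the three climate factors accumulated from the transplant date
to each 8-day composite date: cumulative insolation (MJ m^-2), cumulative
daily maximum temperature and cumulative daily minimum temperature
(degC day).  A seasonal canopy state cannot be a function of a single day's
weather, so running accumulations are the default; an ``instantaneous``
switch is kept for sensitivity checks.

Eleven estimator families are supported: polynomial linear regression,
ridge (alpha 0.1), lasso (alpha 0.01), support vector regression, random
forest, extra trees, gradient boosting, histogram-based gradient boosting,
XGBoost, LightGBM, and the fully connected neural network in
:mod:`ricelai.dnn`.  Scores are coefficients of determination (R^2) on the
scored subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    HistGradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.linear_model import Lasso, LinearRegression, Ridge
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.svm import SVR

from . import metrics
from .crop_model import SeasonConfig, validate_weather
from .dnn import DNNConfig, MLPRegressor
from .exceptions import (
    ConfigError,
    InsufficientDataError,
    InvalidInputError,
    UndefinedStatisticError,
)

__all__ = [
    "FAMILIES",
    "FEATURE_COLUMNS",
    "RegressorSpec",
    "FitResult",
    "build_features",
    "split_train_test",
    "train",
    "evaluate",
    "grid_search_alpha",
    "train_dnn",
    "predict_lai",
]

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = ["cum_srad", "cum_tmax", "cum_tmin"]

FAMILIES = (
    "polynomial_linear",
    "ridge",
    "lasso",
    "svr",
    "random_forest",
    "extra_trees",
    "gradient_boosting",
    "hgb",
    "xgb",
    "lightgbm",
    "dnn",
)

# families whose fit is deterministic for a fixed seed
SEEDABLE = set(FAMILIES) - {"svr"}  # SVR is deterministic anyway (no seed needed)


@dataclass(frozen=True)
class RegressorSpec:
    """One named estimator family plus its hyperparameters and seed."""

    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigError(
                f"unknown regressor family {self.family!r}; choose one of {FAMILIES}"
            )


@dataclass
class FitResult:
    """A trained regressor with its train/test R^2 scores."""

    spec: RegressorSpec
    model: object
    train_score: float
    test_score: float | None = None

    def __post_init__(self):
        if self.train_score > 1 + 1e-12:
            raise InvalidInputError("R^2 scores cannot exceed 1")


def build_features(
    weather_by_pixel: dict,
    lai_obs: pd.DataFrame,
    season_by_pixel,
    *,
    instantaneous: bool = False,
) -> pd.DataFrame:
    """Assemble the per-composite feature table.

    Parameters
    ----------
    weather_by_pixel : dict
        Maps pixel id to its daily weather DataFrame (date, tmax, tmin, srad).
    lai_obs : DataFrame
        Columns pixel_id, date, lai (the target; may carry extra metadata
        columns region and year, which are passed through).
    season_by_pixel : SeasonConfig or dict
        One season configuration, or a mapping pixel id -> SeasonConfig.
    instantaneous : bool
        If True, use the composite-date day's own weather instead of
        accumulations since transplanting (sensitivity switch).

    Returns one row per (pixel, composite date) with columns pixel_id,
    date, cum_srad, cum_tmax, cum_tmin and lai. Composite dates that fall
    before the pixel's transplant date are skipped with a logged count.
    """
    rows = []
    skipped = 0
    for pixel_id, group in lai_obs.groupby("pixel_id", sort=True):
        if pixel_id not in weather_by_pixel:
            raise InvalidInputError(f"no weather series for pixel {pixel_id!r}")
        season = (
            season_by_pixel[pixel_id]
            if isinstance(season_by_pixel, dict)
            else season_by_pixel
        )
        w = validate_weather(weather_by_pixel[pixel_id]).set_index("date")
        transplant = pd.Timestamp(season.transplant_date)
        # accumulate over the days elapsed after transplanting, so a sample
        # k days after transplanting integrates exactly k days of weather
        in_season = w.loc[w.index > transplant]
        csum = in_season[["srad", "tmax", "tmin"]].cumsum()
        zero = pd.Series({"srad": 0.0, "tmax": 0.0, "tmin": 0.0})
        for _, rec in group.iterrows():
            d = pd.Timestamp(rec["date"])
            if d < transplant:
                skipped += 1
                continue
            if d == transplant:
                pass  # nothing accumulated yet
            elif d not in csum.index:
                raise InvalidInputError(
                    f"weather for pixel {pixel_id!r} does not cover {d.date()}"
                )
            if instantaneous:
                src_row = w.loc[d] if d in w.index else zero
            else:
                src_row = zero if d == transplant else csum.loc[d]
            row = {
                "pixel_id": pixel_id,
                "date": d,
                "cum_srad": float(src_row["srad"]),
                "cum_tmax": float(src_row["tmax"]),
                "cum_tmin": float(src_row["tmin"]),
            }
            for meta in ("region", "year"):
                if meta in rec.index:
                    row[meta] = rec[meta]
            if "lai" in rec.index and pd.notna(rec["lai"]):
                row["lai"] = float(rec["lai"])
            rows.append(row)
    if skipped:
        logger.warning("skipped %d samples dated before transplanting", skipped)
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values(["pixel_id", "date"]).reset_index(drop=True)
    return table


def split_train_test(
    table: pd.DataFrame, train_fraction: float = 0.8, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random row split into disjoint, exhaustive train/test tables.

    The train set receives floor(n * train_fraction) rows; the remainder
    goes to test. Reproducible for a given seed.
    """
    if not 0 < train_fraction < 1:
        raise InvalidInputError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n = len(table)
    if n < 5:
        raise InsufficientDataError(f"need at least 5 rows to split, have {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(n * train_fraction))
    train_idx, test_idx = perm[:n_train], perm[n_train:]
    return (
        table.iloc[np.sort(train_idx)].reset_index(drop=True),
        table.iloc[np.sort(test_idx)].reset_index(drop=True),
    )


def _make_estimator(spec: RegressorSpec, profile: str = "paper"):
    """Instantiate the underlying estimator for a spec.

    The ``test`` profile caps ensemble sizes and epochs so unit tests and
    smoke pipelines run at desk scale; the ``paper`` profile uses the full
    settings.
    """
    hp = dict(spec.hyperparameters)
    seed = spec.seed
    fam = spec.family
    small = profile == "test"
    if fam == "polynomial_linear":
        degree = hp.pop("degree", 2)
        return make_pipeline(
            PolynomialFeatures(degree=degree, include_bias=False),
            StandardScaler(),
            LinearRegression(**hp),
        )
    if fam == "ridge":
        # same polynomial basis as the plain linear family, plus an l2 penalty
        return make_pipeline(
            PolynomialFeatures(degree=hp.pop("degree", 2), include_bias=False),
            StandardScaler(),
            Ridge(alpha=hp.pop("alpha", 0.1), **hp),
        )
    if fam == "lasso":
        return make_pipeline(
            PolynomialFeatures(degree=hp.pop("degree", 2), include_bias=False),
            StandardScaler(),
            Lasso(alpha=hp.pop("alpha", 0.01), max_iter=hp.pop("max_iter", 10000), **hp),
        )
    if fam == "svr":
        return make_pipeline(StandardScaler(), SVR(**hp))
    if fam == "random_forest":
        hp.setdefault("n_estimators", 30 if small else 100)
        return RandomForestRegressor(random_state=seed, **hp)
    if fam == "extra_trees":
        hp.setdefault("n_estimators", 30 if small else 100)
        return ExtraTreesRegressor(random_state=seed, **hp)
    if fam == "gradient_boosting":
        hp.setdefault("n_estimators", 30 if small else 100)
        return GradientBoostingRegressor(random_state=seed, **hp)
    if fam == "hgb":
        return HistGradientBoostingRegressor(random_state=seed, **hp)
    if fam == "xgb":
        import xgboost

        hp.setdefault("n_estimators", 30 if small else 100)
        return xgboost.XGBRegressor(random_state=seed, verbosity=0, **hp)
    if fam == "lightgbm":
        import lightgbm

        hp.setdefault("n_estimators", 30 if small else 100)
        return lightgbm.LGBMRegressor(random_state=seed, verbose=-1, **hp)
    if fam == "dnn":
        config = hp.pop("config", None)
        if config is None:
            config = DNNConfig(
                hidden_units=tuple(hp.pop("hidden_units", (100, 300, 1000, 1000, 300, 100))),
                dropout=hp.pop("dropout", 0.17),
                learning_rate=hp.pop("learning_rate", 1e-3),
                epochs=hp.pop("epochs", 200 if small else 1000),
                batch_size=hp.pop("batch_size", 100),
            )
        return MLPRegressor(config=config, seed=seed)
    raise ConfigError(f"unknown family {fam!r}")  # pragma: no cover


def _xy(table: pd.DataFrame):
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidInputError(f"feature table missing columns: {missing}")
    X = table[FEATURE_COLUMNS].astype(float)  # keep names: estimators see a stable schema
    if not np.isfinite(X.to_numpy()).all():
        raise InvalidInputError("non-finite feature value")
    y = None
    if "lai" in table.columns:
        y = table["lai"].to_numpy(dtype=float)
    return X, y


def train(
    spec: RegressorSpec,
    train_table: pd.DataFrame,
    test_table: pd.DataFrame | None = None,
    *,
    profile: str = "paper",
) -> FitResult:
    """Fit one regressor family and score it by R^2.

    ``train_score`` is computed on the training rows; ``test_score`` on the
    held-out rows when a test table is given.
    """
    if len(train_table) < 10:
        raise InsufficientDataError(f"need >= 10 training rows, have {len(train_table)}")
    X, y = _xy(train_table)
    if y is None:
        raise InvalidInputError("training table has no 'lai' target column")
    if np.all(y == y[0]):
        raise UndefinedStatisticError("training target has zero variance")
    est = _make_estimator(spec, profile=profile)
    logger.info("training %s with hyperparameters %s", spec.family, spec.hyperparameters)
    est.fit(X, y)
    result = FitResult(
        spec=spec,
        model=est,
        train_score=metrics.r2_score(y, est.predict(X)),
    )
    if test_table is not None:
        result.test_score = evaluate(result, test_table)
    return result


def evaluate(fit: FitResult, table: pd.DataFrame) -> float:
    """R^2 of a trained regressor on a labelled feature table."""
    X, y = _xy(table)
    if y is None:
        raise InvalidInputError("evaluation table has no 'lai' target column")
    return metrics.r2_score(y, fit.model.predict(X))


def grid_search_alpha(
    family: str,
    alphas,
    table: pd.DataFrame,
    seed: int = 0,
    *,
    train_fraction: float = 0.8,
) -> float:
    """Pick the regularization strength maximizing test R^2 over a grid.

    Ties break toward the smallest alpha.
    """
    if family not in ("ridge", "lasso"):
        raise ConfigError(f"alpha grid search applies to ridge/lasso, not {family!r}")
    alphas = sorted(float(a) for a in alphas)
    if not alphas:
        raise ConfigError("empty alpha grid")
    tr, te = split_train_test(table, train_fraction, seed)
    best_alpha, best_score = None, -np.inf
    for alpha in alphas:
        fit = train(RegressorSpec(family, {"alpha": alpha}, seed), tr, te)
        if fit.test_score > best_score:  # strict: first (smallest) alpha wins ties
            best_alpha, best_score = alpha, fit.test_score
    return best_alpha


def train_dnn(
    train_table: pd.DataFrame,
    test_table: pd.DataFrame | None = None,
    *,
    config: DNNConfig | None = None,
    seed: int = 0,
    profile: str = "paper",
) -> FitResult:
    """Train the fully connected network; thin wrapper over :func:`train`."""
    if len(train_table) < 100:
        raise InsufficientDataError(
            f"DNN training needs >= 100 rows, have {len(train_table)}"
        )
    hp = {} if config is None else {"config": config}
    return train(RegressorSpec("dnn", hp, seed), train_table, test_table, profile=profile)


def predict_lai(fit: FitResult, features: pd.DataFrame) -> np.ndarray:
    """Predict LAI for feature rows; predictions are clipped at zero."""
    X, _ = _xy(features)
    pred = np.asarray(fit.model.predict(X), dtype=float)
    if not np.isfinite(pred).all():
        raise InvalidInputError("regressor produced non-finite predictions")
    return np.clip(pred, 0.0, None)
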