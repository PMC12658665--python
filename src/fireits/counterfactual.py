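"""Stage 1 of the 2-stage interrupted time series: counterfactual fitting.

For one stratum (zone x setting x cause) the engine fits, on pre-event data
only, a hybrid model: a structural seasonal-trend base learner (trend spline
+ day-of-week + annual Fourier harmonics + holiday term) and, optionally, a
gradient-boosted corrector trained on the base learner's residuals using
exogenous covariates and calendar features. Candidate configurations compete
on mean RMSE across rolling-origin cross-validation folds; the winner is
refit on the full pre-period and can predict any post-event date from
calendar and covariate inputs alone — observed post-event counts never enter
the fit, which is what makes the prediction a counterfactual.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import xgboost as xgb

from .scenario import holiday_dates

logger = logging.getLogger(__name__)

_MIN_TRAIN_DAYS = 365


@dataclass(frozen=True)
class ModelConfig:
    """One candidate counterfactual model.

    ``trend_flexibility`` is the number of interior knots of a truncated
    linear trend spline (0 = purely linear trend). ``gb_rounds=0`` keeps the
    residual learner but makes its correction identically zero, which is
    useful for tie-break tests.

    When ``covariates_in_base`` is true (the default) the z-scored
    covariates also enter the base learner as log-linear terms; background
    drivers such as respiratory-virus wastewater levels act multiplicatively
    on visit rates, and the boosted corrector then only has to pick up
    nonlinear remainder structure.
    """

    base_learner: str = "structural_seasonal"
    fourier_order_annual: int = 3
    trend_flexibility: int = 0
    use_holidays: bool = True
    residual_learner: str = "none"
    gb_depth: int = 3
    gb_learning_rate: float = 0.1
    gb_rounds: int = 200
    covariate_names: tuple[str, ...] = ()
    covariates_in_base: bool = True

    def __post_init__(self) -> None:
        if self.base_learner not in ("structural_seasonal", "seasonal_regression"):
            raise ValueError(f"unknown base learner {self.base_learner!r}")
        if self.residual_learner not in ("none", "gradient_boosting"):
            raise ValueError(f"unknown residual learner {self.residual_learner!r}")
        if self.fourier_order_annual < 0:
            raise ValueError("fourier_order_annual must be >= 0")


#: Default candidate grid: small enough for desk-scale cross-validation.
def default_config_grid(covariate_names: Sequence[str] = ()) -> list[ModelConfig]:
    grid = []
    for order in (3, 8):
        for knots in (0, 4):
            grid.append(
                ModelConfig(fourier_order_annual=order, trend_flexibility=knots)
            )
            for depth in (2, 4):
                grid.append(
                    ModelConfig(
                        fourier_order_annual=order,
                        trend_flexibility=knots,
                        residual_learner="gradient_boosting",
                        gb_depth=depth,
                        gb_learning_rate=0.1,
                        gb_rounds=200,
                        covariate_names=tuple(covariate_names),
                    )
                )
    return grid


@dataclass(frozen=True)
class CVScheme:
    n_folds: int = 5
    validation_days: int = 28
    gap_days: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 1 or self.validation_days < 1 or self.gap_days < 0:
            raise ValueError("invalid CV scheme")


@dataclass
class CounterfactualFit:
    config: ModelConfig
    stratum: tuple[str, str, str] | None
    cv_rmse: float
    residuals: pd.Series
    fitted_pre: pd.Series
    predict: Callable[..., pd.Series]
    cv_results: pd.DataFrame = field(repr=False, default=None)
    features: object = field(repr=False, default=None)  # fitted _FeatureMaker
    #: Out-of-sample residuals of the selected config on the CV validation
    #: windows; these reflect true forecast error (in-sample residuals are
    #: optimistic, especially for the boosted corrector) and are what the
    #: Monte Carlo CI resamples by default.
    residuals_cv: pd.Series = field(repr=False, default=None)
    #: Predictions paired with ``residuals_cv`` (for relative-scale resampling).
    fitted_cv: pd.Series = field(repr=False, default=None)


def rmse(observed, predicted) -> float:
    """Root mean squared error between two equal-length series."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size == 0:
        raise ValueError(f"length mismatch or empty: {obs.shape} vs {pred.shape}")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def make_folds(
    pre_dates: pd.DatetimeIndex, scheme: CVScheme
) -> list[tuple[pd.DatetimeIndex, pd.DatetimeIndex]]:
    """Rolling-origin folds over the pre-period.

    Validation windows are the last ``n_folds`` non-overlapping blocks of
    ``validation_days``; each fold trains only on dates ending
    ``gap_days`` before its window. Requires at least 365 training days for
    the earliest fold.
    """
    n = len(pre_dates)
    required = _MIN_TRAIN_DAYS + scheme.gap_days + scheme.n_folds * scheme.validation_days
    if n < required:
        raise ValueError(
            f"pre-period has {n} days but the CV scheme requires >= {required}"
        )
    folds = []
    for k in range(scheme.n_folds):
        val_end = n - (scheme.n_folds - 1 - k) * scheme.validation_days
        val_start = val_end - scheme.validation_days
        train_end = val_start - scheme.gap_days
        folds.append((pre_dates[:train_end], pre_dates[val_start:val_end]))
    return folds


# -- feature construction ------------------------------------------------

class _FeatureMaker:
    """Deterministic calendar/covariate features anchored to the pre-period."""

    def __init__(
        self,
        pre_dates: pd.DatetimeIndex,
        covariates: pd.DataFrame | None,
        covariate_names: Sequence[str],
    ) -> None:
        self.t0 = pre_dates[0]
        self.knot_span = (pre_dates[-1] - self.t0).days / 365.25
        horizon = pre_dates[-1] + pd.Timedelta(days=3 * 366)
        self.holidays = holiday_dates(self.t0.date(), horizon.date())
        self.covariates = covariates
        self.covariate_names = tuple(covariate_names)
        if self.covariate_names:
            pre_cov = covariates.loc[covariates.index.isin(pre_dates), list(self.covariate_names)]
            self.cov_mean = pre_cov.mean()
            self.cov_std = pre_cov.std(ddof=0).replace(0.0, 1.0)

    def base_design(self, dates: pd.DatetimeIndex, config: ModelConfig) -> np.ndarray:
        t = (dates - self.t0).days.to_numpy(dtype=float) / 365.25
        cols = [np.ones_like(t), t]
        if config.trend_flexibility > 0:
            knots = np.linspace(0, self.knot_span, config.trend_flexibility + 2)[1:-1]
            cols.extend(np.maximum(0.0, t - k) for k in knots)
        dow = dates.dayofweek.to_numpy()
        cols.extend((dow == d).astype(float) for d in range(1, 7))
        doy = dates.dayofyear.to_numpy(dtype=float)
        for k in range(1, config.fourier_order_annual + 1):
            w = 2 * np.pi * k * doy / 365.25
            cols.append(np.sin(w))
            cols.append(np.cos(w))
        if config.use_holidays:
            cols.append(dates.isin(self.holidays).astype(float))
        if config.covariates_in_base and config.covariate_names:
            z = (
                self.covariates.reindex(dates)[list(config.covariate_names)]
                - self.cov_mean[list(config.covariate_names)]
            ) / self.cov_std[list(config.covariate_names)]
            cols.extend(z[c].to_numpy(dtype=float) for c in config.covariate_names)
        return np.column_stack(cols)

    def residual_design(self, dates: pd.DatetimeIndex) -> np.ndarray:
        dow = dates.dayofweek.to_numpy()
        doy = dates.dayofyear.to_numpy(dtype=float)
        cols = [
            dow.astype(float),
            dates.isin(self.holidays).astype(float),
            np.sin(2 * np.pi * doy / 365.25),
            np.cos(2 * np.pi * doy / 365.25),
        ]
        if self.covariate_names:
            z = (
                self.covariates.reindex(dates)[list(self.covariate_names)] - self.cov_mean
            ) / self.cov_std
            cols.extend(z[c].to_numpy(dtype=float) for c in self.covariate_names)
        return np.column_stack(cols)


class _HybridModel:
    """Base learner plus optional gradient-boosted residual corrector."""

    def __init__(self, config: ModelConfig, features: _FeatureMaker, seed: int) -> None:
        self.config = config
        self.features = features
        self.seed = seed
        self._base_params: np.ndarray | None = None
        self._booster: xgb.XGBRegressor | None = None
        self.n_clipped = 0

    def fit(self, dates: pd.DatetimeIndex, y: np.ndarray) -> "_HybridModel":
        X = self.features.base_design(dates, self.config)
        if self.config.base_learner == "structural_seasonal":
            model = sm.GLM(y, X, family=sm.families.Poisson())
            self._base_result = model.fit(maxiter=200)
            base_pred = np.asarray(self._base_result.predict(X))
        else:
            self._base_params, *_ = np.linalg.lstsq(X, y, rcond=None)
            base_pred = X @ self._base_params
        if self.config.residual_learner == "gradient_boosting" and self.config.gb_rounds > 0:
            R = self.features.residual_design(dates)
            # Residual signals are weak relative to count noise, so the
            # corrector is regularized (row/column subsampling, minimum
            # child weight) to curb fitting day-level noise.
            self._booster = xgb.XGBRegressor(
                n_estimators=self.config.gb_rounds,
                max_depth=self.config.gb_depth,
                learning_rate=self.config.gb_learning_rate,
                subsample=0.8,
                colsample_bytree=0.8,
                min_child_weight=5,
                reg_lambda=1.0,
                random_state=self.seed,
                n_jobs=1,
                tree_method="hist",
                verbosity=0,
            )
            self._booster.fit(R, y - base_pred)
        return self

    def predict(self, dates: pd.DatetimeIndex) -> np.ndarray:
        X = self.features.base_design(dates, self.config)
        if self.config.base_learner == "structural_seasonal":
            pred = np.asarray(self._base_result.predict(X))
        else:
            pred = X @ self._base_params
        if self._booster is not None:
            pred = pred + self._booster.predict(self.features.residual_design(dates))
        clipped = int(np.sum(pred < 0))
        if clipped:
            self.n_clipped += clipped
            logger.info("clipped %d negative predictions at 0", clipped)
        return np.maximum(pred, 0.0)


def _coerce_series(series) -> pd.Series:
    if isinstance(series, pd.DataFrame):
        s = series.set_index(pd.to_datetime(series["date"]))["count"]
    else:
        s = series.copy()
        s.index = pd.to_datetime(s.index)
    return s.astype(float).sort_index()


def _coerce_covariates(covariates: pd.DataFrame | None) -> pd.DataFrame | None:
    if covariates is None:
        return None
    cov = covariates.copy()
    if "zone" in cov.columns:
        if cov["zone"].nunique() > 1:
            raise ValueError("covariate table spans several zones; filter to the stratum's zone")
        cov = cov.drop(columns=["zone"])
    cov = cov.set_index(pd.to_datetime(cov["date"])).drop(columns=["date"]).sort_index()
    cov.index.name = "date"
    return cov


def fit_counterfactual(
    series,
    covariates: pd.DataFrame | None,
    pre_end: dt.date,
    configs: Sequence[ModelConfig],
    scheme: CVScheme = CVScheme(),
    seed: int = 0,
    stratum: tuple[str, str, str] | None = None,
) -> CounterfactualFit:
    """Select, by cross-validated RMSE, and fit the counterfactual model.

    ``pre_end`` is exclusive: the pre-period is every date strictly before it
    (for an event on Jan 7, pass Jan 7). Ties in mean CV RMSE break toward
    the earlier config in ``configs``.
    """
    if not configs:
        raise ValueError("need at least one candidate config")
    y_all = _coerce_series(series)
    cov = _coerce_covariates(covariates)
    pre = y_all[y_all.index < pd.Timestamp(pre_end)]
    pre_dates = pre.index

    needed = sorted({c for cfg in configs for c in cfg.covariate_names})
    if needed:
        if cov is None:
            raise ValueError("configs use covariates but none were supplied")
        for col in needed:
            if col not in cov.columns:
                raise ValueError(f"covariate column {col!r} missing")
            bad = cov.index[cov[col].isna()]
            if len(bad):
                raise ValueError(
                    f"NaN covariate {col!r} on {bad[0].date().isoformat()}"
                )

    features = _FeatureMaker(pre_dates, cov, needed)
    folds = make_folds(pre_dates, scheme)

    rows = []
    oos: dict[int, list[pd.Series]] = {}
    oos_fit: dict[int, list[pd.Series]] = {}
    for i, cfg in enumerate(configs):
        fold_scores = []
        oos[i] = []
        oos_fit[i] = []
        for train_dates, val_dates in folds:
            model = _HybridModel(cfg, features, seed).fit(
                train_dates, pre.loc[train_dates].to_numpy()
            )
            val_pred = model.predict(val_dates)
            fold_scores.append(rmse(pre.loc[val_dates].to_numpy(), val_pred))
            oos[i].append(pre.loc[val_dates] - val_pred)
            oos_fit[i].append(pd.Series(val_pred, index=val_dates))
        rows.append({"config": cfg, "cv_rmse": float(np.mean(fold_scores))})
    cv_results = pd.DataFrame(rows)
    best_idx = int(np.argmin(cv_results["cv_rmse"].to_numpy()))  # first wins ties
    best = configs[best_idx]

    final = _HybridModel(best, features, seed).fit(pre_dates, pre.to_numpy())
    fitted = pd.Series(final.predict(pre_dates), index=pre_dates, name="fitted")
    residuals = pre - fitted

    def predict(dates, covariates=None) -> pd.Series:
        dates = pd.DatetimeIndex(pd.to_datetime(dates))
        if covariates is not None:
            new_cov = _coerce_covariates(covariates)
            features.covariates = (
                new_cov if features.covariates is None
                else new_cov.combine_first(features.covariates)
            )
        out = final.predict(dates)
        return pd.Series(out, index=dates, name="predicted")

    return CounterfactualFit(
        config=best,
        stratum=stratum,
        cv_rmse=float(cv_results["cv_rmse"].iloc[best_idx]),
        residuals=residuals.rename("residual"),
        fitted_pre=fitted,
        predict=predict,
        cv_results=cv_results,
        features=features,
        residuals_cv=pd.concat(oos[best_idx]).rename("residual_cv"),
        fitted_cv=pd.concat(oos_fit[best_idx]).rename("fitted_cv"),
    )
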