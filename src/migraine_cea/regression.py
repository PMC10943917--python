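"""Utility-by-MMD and work-loss regressions, and labour-cost valuation.

The health-state values of the cohort model come from a linear regression of
EQ-5D-style utility on monthly migraine days (MMD): utility = u0 - b*MMD.
Adverse events subtract a catalogue disutility weighted by per-arm incidence.
Productivity losses come from two further linear regressions (MIDAS absent
days and presenteeism days per 3-month window against MMD), valued at one day
of labour per absent day and a configurable fraction (default one half) per
presenteeism day, at a daily labour cost derived from the monthly wage,
working days per month, and the unemployment rate.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .params import ArmSpec, LinearCoeffs, UtilityModelSpec

MAX_MMD = 28.0
MIDAS_WINDOW_DAYS = 90.0


@dataclass
class FittedLinearModel:
    """One fitted simple linear regression y = intercept + slope_sign*slope*x.

    For the utility model the slope is stored as a positive decrement
    magnitude (``decreasing=True``); work-loss models store the raw slope.
    The 2x2 coefficient covariance feeds multivariate-normal sampling in the
    probabilistic sensitivity analysis.
    """

    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    residual_sd: float
    n_obs: int
    cov: np.ndarray  # covariance of (intercept, slope) as stored
    decreasing: bool = False  # True: predictions use intercept - slope*x

    def predict(self, x: float | np.ndarray) -> float | np.ndarray:
        sign = -1.0 if self.decreasing else 1.0
        return self.intercept + sign * self.slope * x

    def conf_int_slope(self, alpha: float = 0.05) -> tuple[float, float]:
        from scipy import stats

        tcrit = stats.t.ppf(1 - alpha / 2, self.n_obs - 2)
        return (self.slope - tcrit * self.slope_se, self.slope + tcrit * self.slope_se)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": [self.intercept, self.slope],
             "se": [self.intercept_se, self.slope_se]},
            index=["intercept", "slope"],
        )


@dataclass
class WorkLossPrediction:
    """Predicted per-cycle work loss and its monetary value."""

    absent_days_per_cycle: float
    presenteeism_days_per_cycle: float
    valued_cost_eur_per_cycle: float


class SingularDesignError(ValueError):
    """Raised when the regressor has no variation (constant MMD column)."""


def _fit_ols(x: np.ndarray, y: np.ndarray, robust: bool = False) -> FittedLinearModel:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError(f"need at least 3 observations, got {len(x)}")
    if np.ptp(x) == 0:
        raise SingularDesignError("regressor is constant: design matrix is singular")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit(cov_type="HC1" if robust else "nonrobust")
    cov = np.asarray(res.cov_params())
    return FittedLinearModel(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        intercept_se=float(res.bse[0]),
        slope_se=float(res.bse[1]),
        residual_sd=float(np.sqrt(res.scale)),
        n_obs=int(res.nobs),
        cov=cov,
    )


def fit_utility_model(records: pd.DataFrame,
                      mmd_col: str = "mmd",
                      utility_col: str = "utility_observed") -> FittedLinearModel:
    """OLS of observed utility on MMD; slope reported as a positive decrement."""
    m = _fit_ols(records[mmd_col].to_numpy(), records[utility_col].to_numpy())
    flip = np.diag([1.0, -1.0])
    return FittedLinearModel(
        intercept=m.intercept, slope=-m.slope, intercept_se=m.intercept_se,
        slope_se=m.slope_se, residual_sd=m.residual_sd, n_obs=m.n_obs,
        cov=flip @ m.cov @ flip, decreasing=True,
    )


def predict_utility(model: FittedLinearModel | UtilityModelSpec,
                    mmd: float) -> float:
    """Utility at a given MMD level: intercept - slope*MMD, clamped to [0, 1]."""
    if not (0.0 <= mmd <= MAX_MMD):
        raise ValueError(f"mmd {mmd!r} outside the modelled spectrum [0, {MAX_MMD:g}]")
    if isinstance(model, UtilityModelSpec):
        value = model.intercept_u0 - model.slope_per_mmd * mmd
    else:
        value = model.intercept - model.slope * mmd
    return float(min(max(value, 0.0), 1.0))


def expected_ae_disutility(arm: ArmSpec, utility_spec: UtilityModelSpec) -> float:
    """Incidence-weighted utility loss over the assessment period:
    sum over adverse events of incidence x catalogue disutility."""
    total = 0.0
    for name, incidence in arm.ae_incidence.items():
        try:
            entry = utility_spec.ae_disutility[name]
        except KeyError:
            raise KeyError(f"adverse event {name!r} has no disutility catalogue entry") from None
        total += incidence * entry.loss
    return total


def fit_work_loss_models(records: pd.DataFrame,
                         mmd_col: str = "mmd",
                         absent_col: str = "midas_days_absent",
                         presenteeism_col: str = "wpai_presenteeism_pct",
                         presenteeism_is_days: bool = False,
                         ) -> tuple[FittedLinearModel, FittedLinearModel]:
    """Fit absent-days-by-MMD and presenteeism-by-MMD regressions.

    Absent days are overdispersed counts, so heteroscedasticity-robust (HC1)
    standard errors are used.  When ``presenteeism_is_days`` is False the
    presenteeism column is a WPAI percentage and is converted to equivalent
    whole days per 3-month window before fitting (pct/100 x window days is the
    WPAI reading; the packaged default instead models reported presenteeism
    days directly).
    """
    x = records[mmd_col].to_numpy()
    absent = _fit_ols(x, records[absent_col].to_numpy(), robust=True)
    pres_y = records[presenteeism_col].to_numpy(dtype=float)
    if not presenteeism_is_days:
        pres_y = pres_y / 100.0 * MIDAS_WINDOW_DAYS
    pres = _fit_ols(x, pres_y, robust=True)
    return absent, pres


def coeffs_to_model(coeffs: LinearCoeffs, decreasing: bool = False) -> FittedLinearModel:
    """Wrap configured regression coefficients as a fitted-model object.

    With only marginal standard errors available the covariance defaults to
    diagonal (no printed covariances to reproduce).
    """
    return FittedLinearModel(
        intercept=coeffs.intercept, slope=coeffs.slope_per_mmd,
        intercept_se=coeffs.intercept_se, slope_se=coeffs.slope_se,
        residual_sd=0.0, n_obs=3,
        cov=np.diag([coeffs.intercept_se ** 2, coeffs.slope_se ** 2]),
        decreasing=decreasing,
    )


def predict_work_loss_days(model: FittedLinearModel, mmd: float,
                           cycle_length_days: float = 84.0) -> float:
    """Expected work-loss days in one model cycle, floored at zero.

    The regressions are fit on a 3-month (90-day) recall window; predictions
    are rescaled by cycle_length/90.
    """
    days_3mo = model.predict(mmd)
    return max(float(days_3mo), 0.0) * cycle_length_days / MIDAS_WINDOW_DAYS


def daily_labour_cost(wage_monthly: float, working_days: float,
                      unemployment_rate: float) -> float:
    """EUR value of one working day: (wage / working days) x (1 - unemployment)."""
    if wage_monthly <= 0:
        raise ValueError("wage_monthly must be > 0")
    if working_days <= 0:
        raise ValueError("working_days must be > 0")
    if not (0.0 <= unemployment_rate < 1.0):
        raise ValueError("unemployment_rate must be in [0, 1)")
    return wage_monthly / working_days * (1.0 - unemployment_rate)


def indirect_cost_per_cycle(mmd: float,
                            absenteeism_model: FittedLinearModel,
                            presenteeism_model: FittedLinearModel,
                            labour_cost_per_day: float,
                            presenteeism_day_fraction: float = 0.5,
                            cycle_length_days: float = 84.0) -> float:
    """Productivity loss in one cycle: absent days at full value, presenteeism
    days at the configured fraction of a day."""
    absent = predict_work_loss_days(absenteeism_model, mmd, cycle_length_days)
    pres = predict_work_loss_days(presenteeism_model, mmd, cycle_length_days)
    return absent * labour_cost_per_day + pres * presenteeism_day_fraction * labour_cost_per_day
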