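"""Controlled interrupted time series engine.

The design is a segmented linear regression on the weekly series: intercept,
linear trend, a level and slope change switched on at the announcement week, a
level and slope change switched on at the implementation week, two annual
harmonic pairs (period 52.18 weeks), a December-January (Christmas) indicator,
an optional Easter-week indicator, and optionally the control category's
observed series as a covariate. Three analysis designs share this structure:

* analysis 1 isolates the announcement (announcement terms only, window ending
  two years after the announcement);
* analysis 2 isolates the implementation (both interruptions in the design,
  implementation terms counted as the intervention);
* analysis 3 is the whole intervention (both interruptions counted).

Uncertainty uses heteroskedasticity-and-autocorrelation-consistent (Newey-West)
standard errors with the ``floor(4 (n/100)^(2/9))`` lag rule by default; an
AR(1) generalized-least-squares alternative is exposed via ``error_model``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.linear_model import GLSAR

from .aggregate import WeeklySeries
from .weeks import WEEKS_PER_YEAR, christmas_indicator, easter_indicator

ANNOUNCEMENT_COLS = ("post_announcement", "weeks_since_announcement")
IMPLEMENTATION_COLS = ("post_implementation", "weeks_since_implementation")


@dataclass(frozen=True)
class InterruptionSpec:
    """Where the interruptions fall and which analysis design is requested."""

    announcement_week: int
    implementation_week: int
    analysis_id: int = 3
    window: Optional[Tuple[int, int]] = None  # inclusive (first, last) week index
    evaluation_week: Optional[int] = None  # default: last week of window

    def __post_init__(self) -> None:
        if self.analysis_id not in (1, 2, 3):
            raise ValueError("analysis_id must be 1, 2 or 3")
        if self.announcement_week >= self.implementation_week:
            raise ValueError("announcement_week must precede implementation_week")

    def resolve_window(self, n_weeks: int) -> Tuple[int, int]:
        """Default windows: analysis 1 ends two years (104 weeks) after the
        announcement; analyses 2 and 3 span the full series."""
        if self.window is not None:
            lo, hi = self.window
        elif self.analysis_id == 1:
            lo, hi = 0, min(self.announcement_week + 103, n_weeks - 1)
        else:
            lo, hi = 0, n_weeks - 1
        if not 0 <= lo < hi < n_weeks:
            raise ValueError(f"window {(lo, hi)} invalid for a {n_weeks}-week series")
        return lo, hi

    def resolve_evaluation_week(self, n_weeks: int) -> int:
        lo, hi = self.resolve_window(n_weeks)
        week = self.evaluation_week if self.evaluation_week is not None else hi
        if not lo <= week <= hi:
            raise ValueError(f"evaluation week {week} outside window {(lo, hi)}")
        return week

    @property
    def intervention_cols(self) -> Tuple[str, ...]:
        if self.analysis_id == 1:
            return ANNOUNCEMENT_COLS
        if self.analysis_id == 2:
            return IMPLEMENTATION_COLS
        return ANNOUNCEMENT_COLS + IMPLEMENTATION_COLS


@dataclass
class DesignMatrix:
    """Design matrix over the fit window plus the column roles."""

    X: pd.DataFrame  # indexed by week start date
    week_index: np.ndarray  # global week index t for each row
    spec: Optional[InterruptionSpec] = None
    intervention_cols: Tuple[str, ...] = ()
    control_col: Optional[str] = None

    def __post_init__(self) -> None:
        missing = [c for c in self.intervention_cols if c not in self.X.columns]
        if missing:
            raise ValueError(f"intervention columns missing from design: {missing}")

    def counterfactual_exog(self) -> pd.DataFrame:
        """Design with the intervention columns zeroed out."""
        X0 = self.X.copy()
        X0[list(self.intervention_cols)] = 0.0
        return X0

    def row_for_week(self, week: int) -> Tuple[pd.Series, pd.Series]:
        """(observed row, counterfactual row) at global week index ``week``."""
        pos = np.nonzero(self.week_index == week)[0]
        if len(pos) == 0:
            raise ValueError(f"week {week} not in the fit window")
        a = self.X.iloc[pos[0]]
        b = a.copy()
        b[list(self.intervention_cols)] = 0.0
        return a, b


def build_design(
    weeks: pd.DatetimeIndex,
    spec: InterruptionSpec,
    control_series: Optional[WeeklySeries] = None,
    n_harmonics: int = 2,
    christmas: bool = True,
    easter: bool = False,
    period: float = WEEKS_PER_YEAR,
) -> DesignMatrix:
    """Build the segmented-regression design over the spec's fit window.

    ``weeks`` is the full study grid; rows are restricted to the window.
    Analysis 1 includes the announcement terms only (its window must end before
    the implementation); analyses 2 and 3 include both interruptions. Raises on
    rank deficiency (e.g. a constant or deterministic-trend control series) and
    on interruptions falling outside the window.
    """
    n_weeks = len(weeks)
    lo, hi = spec.resolve_window(n_weeks)
    t = np.arange(n_weeks, dtype=float)
    t_a, t_i = spec.announcement_week, spec.implementation_week

    if not lo < t_a <= hi:
        raise ValueError(f"announcement week {t_a} outside fit window {(lo, hi)}")

    cols = {"const": np.ones(n_weeks), "t": t}
    a = (t >= t_a).astype(float)
    cols["post_announcement"] = a
    cols["weeks_since_announcement"] = (t - t_a) * a
    include_implementation = spec.analysis_id in (2, 3)
    if include_implementation:
        if not lo < t_i <= hi:
            raise ValueError(f"implementation week {t_i} outside fit window {(lo, hi)}")
        i = (t >= t_i).astype(float)
        cols["post_implementation"] = i
        cols["weeks_since_implementation"] = (t - t_i) * i
    elif t_i <= hi:
        raise ValueError("analysis 1 window must end before the implementation week")

    for k in range(1, n_harmonics + 1):
        cols[f"sin{k}"] = np.sin(2.0 * np.pi * k * t / period)
        cols[f"cos{k}"] = np.cos(2.0 * np.pi * k * t / period)
    if christmas:
        cols["christmas"] = christmas_indicator(weeks)
    if easter:
        cols["easter"] = easter_indicator(weeks)

    control_col = None
    if control_series is not None:
        cs = control_series.to_series().reindex(weeks)
        if cs.isna().any():
            raise ValueError("control series does not cover the study grid")
        cols["control"] = cs.to_numpy()
        control_col = "control"

    X = pd.DataFrame(cols, index=weeks).iloc[lo : hi + 1]
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient over the window (rank {rank} < {X.shape[1]}); "
            "a constant or collinear control series is a common cause"
        )
    return DesignMatrix(
        X=X,
        week_index=np.arange(lo, hi + 1),
        spec=spec,
        intervention_cols=spec.intervention_cols,
        control_col=control_col,
    )


def newey_west_lags(n: int) -> int:
    """Newey-West truncation lag: floor(4 (n/100)^(2/9))."""
    return int(np.floor(4.0 * (n / 100.0) ** (2.0 / 9.0)))


@dataclass
class CITSFit:
    """A fitted interrupted-time-series model."""

    params: pd.Series
    cov: pd.DataFrame  # autocorrelation-robust covariance of params
    fitted: pd.Series
    residuals: pd.Series
    design: DesignMatrix
    outcome_label: str
    measure: str
    unit: str
    error_model: str
    hac_lags: Optional[int] = None
    ar1_rho: Optional[float] = None

    @property
    def nobs(self) -> int:
        return len(self.fitted)


def fit(
    design: DesignMatrix,
    outcome: WeeklySeries,
    error_model: str = "hac",
) -> CITSFit:
    """Fit the design to an outcome series.

    ``error_model='hac'`` uses OLS coefficients with Newey-West covariance at
    the standard lag rule; ``'ar1-gls'`` uses iterated AR(1) generalized least
    squares (Prais-Winsten style via GLSAR).
    """
    y = outcome.to_series().reindex(design.X.index)
    if y.isna().any():
        raise ValueError("outcome has missing values in the fit window; weeks must be complete")
    if not np.isfinite(y.to_numpy()).all():
        raise ValueError("outcome values must be finite")
    n, k = design.X.shape
    if n < k + 10:
        raise ValueError(f"window of {n} weeks is too short for {k} parameters (+10 required)")

    hac_lags = None
    ar1_rho = None
    if error_model == "hac":
        hac_lags = newey_west_lags(n)
        res = sm.OLS(y, design.X).fit(cov_type="HAC", cov_kwds={"maxlags": hac_lags})
        params = res.params
        cov = res.cov_params()
    elif error_model == "ar1-gls":
        res = GLSAR(y, design.X, rho=1).iterative_fit(maxiter=50)
        params = res.params
        cov = res.cov_params()
        ar1_rho = float(res.model.rho[0])
    else:
        raise ValueError(f"unknown error_model {error_model!r}")

    fitted = pd.Series(design.X.to_numpy() @ params.to_numpy(), index=design.X.index, name="fitted")
    residuals = y - fitted
    return CITSFit(
        params=params,
        cov=pd.DataFrame(np.asarray(cov), index=params.index, columns=params.index),
        fitted=fitted,
        residuals=residuals,
        design=design,
        outcome_label=outcome.label,
        measure=outcome.measure,
        unit=outcome.unit,
        error_model=error_model,
        hac_lags=hac_lags,
        ar1_rho=ar1_rho,
    )


def project_counterfactual(fit_result: CITSFit) -> WeeklySeries:
    """Model projection with the analysis' intervention terms set to zero.

    Non-intervention terms (trend, seasonality, holiday indicators, control)
    are kept at their observed values, so the counterfactual equals the fitted
    prediction for every week before the first zeroed term activates.
    """
    X0 = fit_result.design.counterfactual_exog()
    values = X0.to_numpy() @ fit_result.params.to_numpy()
    n = len(values)
    return WeeklySeries(
        label=f"{fit_result.outcome_label} (counterfactual)",
        measure=fit_result.measure,
        weeks=X0.index,
        values=values,
        n_households=np.full(n, -1),
        unit=fit_result.unit,
    )


def fit_summary_frame(fit_result: CITSFit) -> pd.DataFrame:
    """Coefficients and robust SEs as a writable table."""
    se = np.sqrt(np.diag(fit_result.cov.to_numpy()))
    return pd.DataFrame(
        {
            "coefficient": fit_result.params,
            "se": se,
            "ci_low": fit_result.params - 1.96 * se,
            "ci_high": fit_result.params + 1.96 * se,
        }
    )
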