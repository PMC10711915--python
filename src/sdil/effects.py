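"""Headline effect quantities from a fitted interrupted time series model.

The absolute change versus counterfactual at the evaluation week is a linear
contrast c'beta of the intervention coefficients (indicators at 1, elapsed
weeks at their evaluation-week values), with SE sqrt(c' Sigma c). The relative
change is the ratio of two linear predictions, 100*(y_obs - y_cf)/y_cf, with a
first-order delta-method variance. When a projected counterfactual crosses
zero before the end of the window, evaluation moves back to the last week with
a positive counterfactual and the estimate is flagged as degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .aggregate import WeeklySeries
from .cits import CITSFit, project_counterfactual
from .synthetic import DegenerateCounterfactualError

Z95 = 1.96  # normal 95% quantile; weekly n is large enough to skip t corrections

#: Mean UK household size used for per-person conversions.
UK_HOUSEHOLD_SIZE = 2.4


@dataclass
class EffectEstimate:
    """Absolute and relative change versus counterfactual at one week."""

    category: str
    measure: str
    analysis_id: int
    evaluation_week: int
    absolute_change: float
    absolute_se: float
    absolute_ci: Tuple[float, float]
    relative_change_pct: float
    relative_ci: Tuple[float, float]
    counterfactual_value: float
    degenerate_flag: bool = False
    unit: str = "mL"

    def significant(self) -> bool:
        """95% CI for the absolute change excludes zero."""
        lo, hi = self.absolute_ci
        return lo > 0 or hi < 0


def _evaluation_week(fit: CITSFit) -> int:
    spec = fit.design.spec
    if spec is None:
        raise ValueError("fit has no interruption spec")
    last_global = int(fit.design.week_index[-1])
    return spec.resolve_evaluation_week(last_global + 1)


def absolute_effect(fit: CITSFit, evaluation_week: Optional[int] = None) -> Tuple[float, float]:
    """(estimate, SE) of the intervention contrast at the evaluation week."""
    week = _evaluation_week(fit) if evaluation_week is None else evaluation_week
    a, b = fit.design.row_for_week(week)
    c = (a - b).to_numpy()
    beta = fit.params.to_numpy()
    est = float(c @ beta)
    se = float(np.sqrt(c @ fit.cov.to_numpy() @ c))
    return est, se


def relative_effect(fit: CITSFit, evaluation_week: Optional[int] = None) -> Tuple[float, Tuple[float, float]]:
    """Relative change % with a delta-method 95% CI.

    Both the observed and counterfactual values are model predictions (linear
    forms of beta); the gradient of r = 100*(a'b - b'b)/b'b with respect to
    beta is 100*(y_cf * a - y_obs * b)/y_cf^2.
    """
    week = _evaluation_week(fit) if evaluation_week is None else evaluation_week
    a, b = fit.design.row_for_week(week)
    a, b = a.to_numpy(), b.to_numpy()
    beta = fit.params.to_numpy()
    y_obs = float(a @ beta)
    y_cf = float(b @ beta)
    if y_cf <= 0:
        raise DegenerateCounterfactualError(
            f"counterfactual at week {week} is {y_cf:.3f} <= 0; evaluate at "
            "last_positive_counterfactual_week instead"
        )
    r = 100.0 * (y_obs - y_cf) / y_cf
    g = 100.0 * (y_cf * a - y_obs * b) / y_cf**2
    var = float(g @ fit.cov.to_numpy() @ g)
    half = Z95 * np.sqrt(var)
    return r, (r - half, r + half)


def last_positive_counterfactual_week(cf: WeeklySeries, week_index: Optional[np.ndarray] = None) -> int:
    """Largest (global) week index at which the counterfactual is positive."""
    if len(cf) == 0:
        raise ValueError("empty counterfactual series")
    idx = np.asarray(week_index) if week_index is not None else np.arange(len(cf))
    positive = np.nonzero(cf.values > 0)[0]
    if len(positive) == 0:
        raise DegenerateCounterfactualError("counterfactual is never positive")
    return int(idx[positive[-1]])


def estimate_effect(fit: CITSFit, evaluation_week: Optional[int] = None) -> EffectEstimate:
    """Full effect estimate, applying the positive-counterfactual rule.

    If the counterfactual at the requested evaluation week is non-positive,
    evaluation moves to the last week with a positive counterfactual and the
    ``degenerate_flag`` is set.
    """
    spec = fit.design.spec
    week = _evaluation_week(fit) if evaluation_week is None else evaluation_week
    cf = project_counterfactual(fit)
    cf_at = dict(zip(fit.design.week_index, cf.values))
    degenerate = False
    if cf_at[week] <= 0:
        week = last_positive_counterfactual_week(cf, fit.design.week_index)
        degenerate = True
    est, se = absolute_effect(fit, week)
    rel, rel_ci = relative_effect(fit, week)
    return EffectEstimate(
        category=fit.outcome_label,
        measure=fit.measure,
        analysis_id=spec.analysis_id if spec is not None else 0,
        evaluation_week=week,
        absolute_change=est,
        absolute_se=se,
        absolute_ci=(est - Z95 * se, est + Z95 * se),
        relative_change_pct=rel,
        relative_ci=rel_ci,
        counterfactual_value=float(cf_at[week]),
        degenerate_flag=degenerate,
        unit=fit.unit,
    )


def per_person(value_per_household: float, household_size: float = UK_HOUSEHOLD_SIZE) -> float:
    """Convert a per-household-per-week value to per person per week."""
    if household_size <= 0:
        raise ValueError("household_size must be > 0")
    return value_per_household / household_size


def sugar_volume_equivalence(
    sugar_change_g: float,
    volume_change_ml: float,
    reference_concentration_g_per_100ml: float,
) -> Tuple[float, float]:
    """Express a sugar change as a drink-replacement equivalence.

    Returns ``(replaced_volume, replacement_volume)``: the mL of a drink at the
    reference sugar concentration whose removal accounts for the sugar change,
    and the mL of sugar-free alternative that also absorbs the volume change.
    """
    if reference_concentration_g_per_100ml <= 0:
        raise ValueError("reference concentration must be > 0")
    replaced = abs(sugar_change_g) / (reference_concentration_g_per_100ml / 100.0)
    return replaced, replaced + volume_change_ml


def effects_table(estimates) -> pd.DataFrame:
    """Flatten EffectEstimates into the report layout (one row per estimate)."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "category": e.category,
                "measure": e.measure,
                "analysis": e.analysis_id,
                "evaluation_week": e.evaluation_week,
                "absolute_change": round(e.absolute_change, 1),
                "absolute_ci_low": round(e.absolute_ci[0], 1),
                "absolute_ci_high": round(e.absolute_ci[1], 1),
                "relative_change_pct": round(e.relative_change_pct, 1),
                "relative_ci_low": round(e.relative_ci[0], 1),
                "relative_ci_high": round(e.relative_ci[1], 1),
                "counterfactual_value": round(e.counterfactual_value, 1),
                "degenerate_flag": e.degenerate_flag,
                "significant": e.significant(),
                "unit": e.unit,
            }
        )
    return pd.DataFrame(rows)
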