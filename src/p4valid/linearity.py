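"""Reportable-range (linearity) assessment.

Ordinary least squares of the measured level means on the spiked (true)
concentrations, with two-sided t-tests of slope and intercept, a paired
t-test of measured-minus-spiked against zero, and bias flags:

* constant bias: intercept significantly different from 0 (p < alpha,
  equivalently 0 outside its 95% CI);
* proportional bias: 95% CI of the slope excludes 1.

Because the regression direction is a perennial source of confusion in
method validation, the fit also reports the reverse regression (spiked on
measured) so a report can print both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .precision import AnalysisError

__all__ = ["LinearityFit", "fit_linearity"]


@dataclass
class LinearityFit:
    slope: float
    slope_p: float
    slope_ci: tuple[float, float]
    intercept: float
    intercept_p: float
    intercept_ci: tuple[float, float]
    r_squared: float
    paired_t_p: float
    constant_bias_present: bool
    proportional_bias_present: bool
    reverse_slope: float
    reverse_intercept: float
    n_levels: int
    alpha: float = 0.05
    meta: dict = field(default_factory=dict)


def _clean_p(p: float, estimate: float, scale: float) -> float:
    """t-test p-value with the zero-residual degenerate case made sane."""
    if math.isnan(p):
        # exact fit: the estimate is either exactly the null or infinitely far
        return 1.0 if abs(estimate) <= 1e-12 * max(1.0, scale) else 0.0
    return float(p)


def fit_linearity(
    level_means: Mapping[float, float] | None = None,
    *,
    spiked: Sequence[float] | None = None,
    measured: Sequence[float] | None = None,
    alpha: float = 0.05,
) -> LinearityFit:
    """Fit measured level means against spiked concentrations.

    ``level_means`` maps spiked concentration -> mean measured value
    (alternatively pass ``spiked``/``measured`` arrays).  The control
    (spiked = 0) is excluded; at least three spiked levels are required.
    """
    if level_means is not None:
        pts = {float(k): float(v) for k, v in level_means.items() if float(k) > 0}
        x = np.array(sorted(pts))
        y = np.array([pts[k] for k in x])
    else:
        if spiked is None or measured is None:
            raise AnalysisError("give level_means or both spiked and measured")
        x = np.asarray(spiked, dtype=float)
        y = np.asarray(measured, dtype=float)
        keep = x > 0
        x, y = x[keep], y[keep]
    if x.size < 3:
        raise AnalysisError("linearity fit needs >= 3 spiked levels")
    if np.ptp(x) == 0:
        raise AnalysisError("zero variance in spiked concentrations")
    if np.isnan(y).any():
        raise AnalysisError("measured means must be uncensored")

    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    intercept, slope = fit.params
    p_int, p_slope = fit.pvalues
    ci = fit.conf_int(alpha=alpha)
    int_ci = (float(ci[0][0]), float(ci[0][1]))
    slope_ci = (float(ci[1][0]), float(ci[1][1]))
    scale = float(np.abs(y).max())
    p_int = _clean_p(p_int, intercept, scale)
    p_slope = _clean_p(p_slope, slope, scale)

    diffs = y - x
    if np.allclose(diffs, diffs[0]) and np.ptp(diffs) == 0 and abs(diffs[0]) < 1e-12 * max(1.0, scale):
        paired_p = 1.0  # measured identical to spiked: no detectable deviation
    else:
        t_res = stats.ttest_rel(y, x)
        paired_p = _clean_p(float(t_res.pvalue), float(diffs.mean()), scale)

    # reverse direction: spiked regressed on measured
    rfit = sm.OLS(x, sm.add_constant(y)).fit()
    r_intercept, r_slope = rfit.params

    return LinearityFit(
        slope=float(slope),
        slope_p=p_slope,
        slope_ci=slope_ci,
        intercept=float(intercept),
        intercept_p=p_int,
        intercept_ci=int_ci,
        r_squared=float(fit.rsquared),
        paired_t_p=paired_p,
        constant_bias_present=bool(p_int < alpha),
        proportional_bias_present=not (slope_ci[0] <= 1.0 <= slope_ci[1]),
        reverse_slope=float(r_slope),
        reverse_intercept=float(r_intercept),
        n_levels=int(x.size),
        alpha=alpha,
        meta={
            "direction": "measured (y) on spiked (x); reverse_* is spiked on measured",
            "proportional_rule": "95% CI of slope excludes 1",
        },
    )
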