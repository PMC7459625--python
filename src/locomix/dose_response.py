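"""Dose-response summaries of a fitted activity model.

Four views of the fitted mean function: the magnitude of the initial
decrease at day 0 with a delta-method confidence interval, the
dose-specific recovery rate, fitted trend curves over a day grid, and the
time until a chosen fraction of the initial decrease remains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimator import FitResult
from .model import mean_activity, recovery_rate as _rate_fn

__all__ = [
    "DoseResponseEstimate",
    "initial_decrease",
    "recovery_rate",
    "fitted_trend",
    "recovery_time",
    "dose_response_table",
    "observed_initial_drops",
]


@dataclass(frozen=True)
class DoseResponseEstimate:
    """Initial decrease at day 0 for one dose, with 95% CI and recovery rate."""

    dose: float
    decrease: float
    ci_lower: float
    ci_upper: float
    recovery_rate: float


def initial_decrease(dose: float, result: FitResult,
                     level: float = 0.95) -> DoseResponseEstimate:
    """Magnitude of the day-0 activity decrease at a dose, with delta-method CI.

    The decrease is ``beta1*D + beta2*D^2`` (log10-activity units); its
    variance is propagated from the fitted covariance of (beta1, beta2)
    with gradient (D, D^2).  At dose 0 the decrease is exactly 0 with a
    zero-width interval.
    """
    b1 = result.theta.beta1
    b2 = result.theta.beta2
    dec = b1 * dose + b2 * dose * dose
    rate = float(_rate_fn(dose, result.theta))
    if dose == 0:
        return DoseResponseEstimate(0.0, 0.0, 0.0, 0.0, rate)

    grad_names = [n for n in ("beta1", "beta2") if n in result.spec.free_fixed]
    grads = {"beta1": dose, "beta2": dose * dose}
    cov = result.cov_params
    if cov is None or any(n not in cov.index for n in grad_names):
        warnings.warn(
            f"parameter covariance unavailable; CI missing for dose {dose}"
        )
        return DoseResponseEstimate(dose, float(dec), np.nan, np.nan, rate)
    g = np.array([grads[n] for n in grad_names])
    sub = cov.loc[grad_names, grad_names].to_numpy()
    var = float(g @ sub @ g)
    if var < 0:
        warnings.warn(f"negative delta-method variance at dose {dose}")
        return DoseResponseEstimate(dose, float(dec), np.nan, np.nan, rate)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return DoseResponseEstimate(
        dose, float(dec), float(dec - half), float(dec + half), rate
    )


def recovery_rate(dose: float, result: FitResult) -> float:
    """Recovery rate r(D) = omega1 * exp(-omega2 (D - D0)), per day.

    When ``omega2`` is dropped from the model the rate is ``omega1`` for
    every dose (dose-independent recovery).
    """
    return float(_rate_fn(dose, result.theta))


def fitted_trend(days, dose: float, result: FitResult) -> pd.DataFrame:
    """Fitted mean log10 activity over a (possibly fine) day grid."""
    days = np.asarray(days, dtype=float)
    fitted = mean_activity(days, np.full_like(days, dose), result.theta)
    return pd.DataFrame({"dose_gy": dose, "day": days, "fitted": fitted})


def recovery_time(dose: float, result: FitResult,
                  fraction: float = 0.05) -> float:
    """Days until the residual decrease falls to ``fraction`` of its day-0 size.

    From the exponential decay the closed form is
    ``t* = -log(fraction) / r(D)``.  The "recovered" threshold is a
    convention (default: 5% of the initial decrease remaining) exposed as
    a parameter, since no standard definition exists.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    r = float(_rate_fn(dose, result.theta))
    if r <= 0:
        raise ValueError(f"recovery undefined: rate r({dose}) = {r} <= 0")
    dec = result.theta.beta1 * dose + result.theta.beta2 * dose * dose
    if dec <= 0:
        raise ValueError(
            f"recovery undefined: initial decrease at dose {dose} is {dec}"
        )
    return float(-np.log(fraction) / r)


def dose_response_table(result: FitResult, doses,
                        level: float = 0.95) -> pd.DataFrame:
    """Initial-decrease estimates with CIs for several doses (CSV-ready)."""
    rows = []
    for d in doses:
        est = initial_decrease(float(d), result, level=level)
        rows.append(
            {
                "dose_gy": est.dose,
                "decrease": est.decrease,
                "ci_lower": est.ci_lower,
                "ci_upper": est.ci_upper,
                "recovery_rate": est.recovery_rate,
            }
        )
    return pd.DataFrame(rows)


def observed_initial_drops(result: FitResult, panel: pd.DataFrame
                           ) -> pd.DataFrame:
    """Per-animal observed day-0 drops from the fitted baseline.

    Reconstruction for plotting against the fitted dose-response curve:
    fitted baseline at day 0 minus each animal's observed day-0 log
    activity.  Not used in estimation.
    """
    at0 = panel[panel["day"] == 0]
    baseline = float(mean_activity(0.0, 0.0, result.theta))
    return pd.DataFrame(
        {
            "animal_id": at0["animal_id"].to_numpy(),
            "dose_gy": at0["dose_gy"].to_numpy(),
            "observed_drop": baseline - at0["log_activity"].to_numpy(),
        }
    )
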