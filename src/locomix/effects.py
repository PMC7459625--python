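"""Random-effect prediction, variance decomposition and diagnostics.

Given a fitted mixed model, the animal effects delta_i and day effects
eta_t are predicted by their posterior means (BLUPs) under the fitted
Gaussian model,

    (delta_hat, eta_hat) = G Z' Omega^{-1} (y - mu_hat),

where ``G`` is the random-effect prior covariance (``psi2`` for animals,
``phi2`` for days) and ``Z`` the incidence of effects on cells.  The
per-cell residual is then defined through the exact cell identity

    y_it - f_hat(t | D_i) = delta_hat_i + eta_hat_t + eps_hat_it.

Posterior means shrink raw group deviations toward zero, the more so the
smaller the corresponding variance component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from statsmodels.stats.stattools import durbin_watson as _dw_statistic

from .model import VarianceComponents, covariance_matrix, mean_activity
from .estimator import FitResult
from .panel import validate_panel

__all__ = [
    "RandomEffectPredictions",
    "predict_random_effects",
    "variance_shares",
    "residual_summary",
    "durbin_watson",
]


@dataclass
class RandomEffectPredictions:
    """Posterior means of the crossed random effects plus residuals.

    ``animal_table`` has one row per animal (animal_id, dose_gy,
    delta_hat); ``day_table`` one row per observed day (day, eta_hat);
    ``residual_table`` one row per cell (animal_id, day, residual).
    """

    animal_table: pd.DataFrame
    day_table: pd.DataFrame
    residual_table: pd.DataFrame

    @property
    def delta_hat(self) -> np.ndarray:
        return self.animal_table["delta_hat"].to_numpy()

    @property
    def eta_hat(self) -> np.ndarray:
        return self.day_table["eta_hat"].to_numpy()

    @property
    def residuals(self) -> np.ndarray:
        return self.residual_table["residual"].to_numpy()


def predict_random_effects(result: FitResult, panel: pd.DataFrame,
                           ) -> RandomEffectPredictions:
    """Posterior-mean (BLUP) prediction of animal and day effects.

    Requires a mixed-model fit; an ordinary-regression fit has no random
    effects to predict and raises ``ValueError``.
    """
    if not result.spec.mixed:
        raise ValueError(
            "ordinary non-linear regression fit has no random effects to "
            "predict"
        )
    panel = validate_panel(panel)
    y = panel["log_activity"].to_numpy()
    day = panel["day"].to_numpy()
    dose = panel["dose_gy"].to_numpy()
    resid0 = y - mean_activity(day, dose, result.theta)

    a_codes, animals = pd.factorize(panel["animal_id"], sort=True)
    d_codes, days = pd.factorize(panel["day"], sort=True)
    delta = result.delta
    omega = covariance_matrix(a_codes, d_codes, delta)
    w = linalg.cho_solve(linalg.cho_factor(omega, lower=True), resid0)

    delta_hat = delta.psi2 * np.bincount(a_codes, weights=w,
                                         minlength=len(animals))
    eta_hat = delta.phi2 * np.bincount(d_codes, weights=w,
                                       minlength=len(days))
    eps_hat = resid0 - delta_hat[a_codes] - eta_hat[d_codes]

    dose_per_animal = (
        panel.groupby("animal_id", sort=True)["dose_gy"].first().to_numpy()
    )
    animal_table = pd.DataFrame(
        {"animal_id": np.asarray(animals), "dose_gy": dose_per_animal,
         "delta_hat": delta_hat}
    )
    day_table = pd.DataFrame({"day": np.asarray(days), "eta_hat": eta_hat})
    residual_table = pd.DataFrame(
        {"animal_id": panel["animal_id"], "day": panel["day"],
         "residual": eps_hat}
    )
    return RandomEffectPredictions(animal_table, day_table, residual_table)


def variance_shares(delta: VarianceComponents):
    """Percentage share of each variance component in the total.

    Returns ``(unrounded, display)``: the exact percentages and the
    nearest-integer display values, ordered (animal, day, error).
    """
    comps = np.array([delta.psi2, delta.phi2, delta.sigma2], dtype=float)
    total = comps.sum()
    if total <= 0:
        raise ValueError("all variance components are zero")
    shares = 100.0 * comps / total
    return shares, tuple(int(round(s)) for s in shares)


def residual_summary(residuals) -> dict:
    """Distribution summary of residuals (SD, quartiles, Tukey whiskers).

    The SD is the population standard deviation (ddof = 0) of the
    residual vector; whiskers are the most extreme values within 1.5 IQR
    of the quartiles, for boxplot-style export.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size == 0:
        raise ValueError("no residuals")
    q1, med, q3 = np.percentile(r, [25, 50, 75])
    iqr = q3 - q1
    in_lo = r[r >= q1 - 1.5 * iqr]
    in_hi = r[r <= q3 + 1.5 * iqr]
    return {
        "n": int(r.size),
        "mean": float(r.mean()),
        "sd": float(r.std(ddof=0)),
        "min": float(r.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(r.max()),
        "whisker_low": float(in_lo.min()) if in_lo.size else float(r.min()),
        "whisker_high": float(in_hi.max()) if in_hi.size else float(r.max()),
    }


def durbin_watson(eta_hat, n_permutations: int = 10_000, seed: int = 0):
    """Durbin-Watson statistic of the ordered day effects + permutation p.

    DW = sum_t (eta_t - eta_{t-1})^2 / sum_t eta_t^2, in [0, 4], about 2
    under no serial correlation.  The predicted day effects are not
    ordinary regression residuals, so the classical DW null tables do not
    apply; the p-value is instead a two-sided permutation tail: the
    fraction of random reorderings whose DW is at least as far from 2 as
    the observed one.  This is an approximation chosen here, not a
    standard DW test.
    """
    eta = np.asarray(eta_hat, dtype=float)
    if eta.size < 3:
        raise ValueError("need at least 3 ordered day effects")
    denom = float(eta @ eta)
    if denom == 0:
        raise ValueError("all day effects are zero; DW undefined")
    dw = float(_dw_statistic(eta))
    rng = np.random.default_rng(seed)
    dist = np.empty(n_permutations)
    for b in range(n_permutations):
        dist[b] = _dw_statistic(eta[rng.permutation(eta.size)])
    obs_dev = abs(dw - 2.0)
    p = (1.0 + np.sum(np.abs(dist - 2.0) >= obs_dev)) / (n_permutations + 1.0)
    return dw, float(p)
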