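"""Maximum-likelihood fitting of the activity model.

The central object is :class:`ActivityNLMM`, a scikit-learn style
estimator: configuration in ``__init__``, data in ``fit(X, y)``, fitted
quantities in trailing-underscore attributes, so the model composes with
sklearn pipelines and ``clone``/``get_params``.  The module-level
functions (:func:`fit`, :func:`select_model`, :func:`wald_interval`,
:func:`one_sided_p`) are thin wrappers for panel-frame workflows.

Estimation is direct maximum likelihood (not REML): the exact Gaussian
log-likelihood under the crossed-random-effects covariance is maximised
with L-BFGS-B over the free fixed effects and the variance components.
Positivity-constrained parameters (``omega1`` and the variance
components) are optimised on the log scale and reported on the natural
scale.  Standard errors come from the inverse of the numerically
differentiated observed information at the optimum, mapped back to the
natural scale by the delta method; variance-component standard errors are
reported but should be treated as approximate.

.. note::
   **p-value convention.**  Reported p-values are *one-sided* normal
   tail probabilities ``p = 1 - Phi(|estimate| / SE)``.  This is
   unconventional (most software reports two-sided Wald tests) but is the
   convention of the reference analysis this package reproduces; double
   the values for a two-sided test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.tools.numdiff import approx_hess

from .model import (
    FIXED_NAMES,
    VARIANCE_NAMES,
    D0_DEFAULT,
    FULL_NLMM,
    FixedEffects,
    ModelSpec,
    VarianceComponents,
    loglik_residuals,
    mean_activity,
    params_from_dict,
    params_to_dict,
)
from .panel import validate_panel

__all__ = [
    "ActivityNLMM",
    "FitResult",
    "ModelSelection",
    "fit",
    "select_model",
    "standard_errors",
    "wald_interval",
    "one_sided_p",
    "observed_information",
]

#: Parameters optimised (and reported) on the log scale.
_LOG_SCALE = frozenset({"omega1", "psi2", "phi2", "sigma2"})

_VAR_FLOOR = 1e-10


@dataclass
class FitResult:
    """Container for one maximum-likelihood fit.

    Satisfies the information-criterion identities
    ``aic = -2*loglik + 2*k_params`` and
    ``bic = -2*loglik + k_params*log(n_obs)``.
    """

    spec: ModelSpec
    theta: FixedEffects
    delta: VarianceComponents
    loglik: float
    aic: float
    bic: float
    n_obs: int
    k_params: int
    converged: bool
    se: dict = field(default_factory=dict)
    cov_params: pd.DataFrame | None = None
    n_iter: int = 0
    message: str = ""

    @property
    def param_names(self) -> tuple[str, ...]:
        return self.spec.free_fixed + self.spec.variance_names

    def estimate(self, name: str) -> float:
        if name in FIXED_NAMES:
            return getattr(self.theta, name)
        return getattr(self.delta, name)

    def table(self, level: float = 0.95) -> pd.DataFrame:
        """Parameter table: estimate, SE, Wald CI, one-sided p (fixed effects)."""
        rows = []
        for name in self.param_names:
            est = self.estimate(name)
            se = self.se.get(name, np.nan)
            lo, hi = wald_interval(est, se, level) if np.isfinite(se) else (np.nan, np.nan)
            p = one_sided_p(est, se) if np.isfinite(se) else np.nan
            rows.append(
                {
                    "parameter": name,
                    "estimate": est,
                    "se": se,
                    "ci_lower": lo,
                    "ci_upper": hi,
                    "p_value": p,
                    "kind": "fixed" if name in FIXED_NAMES else "variance",
                }
            )
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        out = {
            "spec": self.spec.as_dict(),
            "params": params_to_dict(self.theta, self.delta),
            "se": {k: float(v) for k, v in self.se.items()},
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "bic": float(self.bic),
            "n_obs": int(self.n_obs),
            "k_params": int(self.k_params),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "message": self.message,
        }
        if self.cov_params is not None:
            out["cov_params"] = {
                "names": list(self.cov_params.index),
                "matrix": self.cov_params.to_numpy().tolist(),
            }
        return out

    @classmethod
    def from_json_dict(cls, d: dict) -> "FitResult":
        spec = ModelSpec(**d["spec"])
        theta, delta = params_from_dict(d["params"])
        if delta is None:
            delta = VarianceComponents(0.0, 0.0, float(d["params"]["sigma2"]))
        cov = None
        if "cov_params" in d:
            names = d["cov_params"]["names"]
            cov = pd.DataFrame(
                np.asarray(d["cov_params"]["matrix"], dtype=float),
                index=names,
                columns=names,
            )
        return cls(
            spec=spec,
            theta=theta,
            delta=delta,
            loglik=float(d["loglik"]),
            aic=float(d["aic"]),
            bic=float(d["bic"]),
            n_obs=int(d["n_obs"]),
            k_params=int(d["k_params"]),
            converged=bool(d["converged"]),
            se={k: float(v) for k, v in d.get("se", {}).items()},
            cov_params=cov,
            n_iter=int(d.get("n_iter", 0)),
            message=d.get("message", ""),
        )


def wald_interval(estimate: float, se: float, level: float = 0.95):
    """Normal-approximation confidence interval ``estimate ± z * se``."""
    if not se > 0:
        raise ValueError(f"se must be positive, got {se}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return estimate - z * se, estimate + z * se


def one_sided_p(estimate: float, se: float) -> float:
    """One-sided normal tail probability ``1 - Phi(|estimate| / se)``.

    See the module note: this is deliberately one-sided; double for the
    conventional two-sided test.
    """
    if not se > 0:
        raise ValueError(f"se must be positive, got {se}")
    return float(stats.norm.sf(abs(estimate) / se))


def observed_information(loglik_fn, x: np.ndarray) -> np.ndarray:
    """Numerically differentiated observed information -H[loglik] at x."""
    x = np.asarray(x, dtype=float)
    return -approx_hess(x, loglik_fn)


class ActivityNLMM(RegressorMixin, BaseEstimator):
    """Non-linear (mixed) model of post-irradiation locomotor activity.

    Parameters
    ----------
    free_xi1, free_xi2 : bool
        Free the linear / quadratic baseline drift terms.
    free_beta2 : bool
        Free the quadratic dose term of the initial decrease.
    free_omega2 : bool
        Free the dose modulation of the recovery rate.
    mixed : bool
        True for the mixed model (animal and day random effects); False
        for the ordinary non-linear regression limit psi2 = phi2 = 0.
    d0 : float
        Centering dose in Gy (configuration, never estimated).
    tol : float
        Convergence tolerance on the objective Q = -2 loglik.
    max_iter : int
        L-BFGS-B iteration cap.
    n_restarts : int
        Jittered restarts attempted when the first optimisation does not
        converge.
    compute_se : bool
        Compute the observed-information covariance and standard errors.
    init : dict or None
        Optional starting values by parameter name (natural scale),
        overriding the data-driven defaults.
    random_state : int
        Seed for the restart jitter.

    ``fit(X, y)`` takes ``X`` either as a DataFrame with columns
    ``animal_id``, ``day``, ``dose_gy`` or as an (n, 3) array with
    columns (animal code, day, dose); ``y`` is the log10 activity.

    Fitted attributes: ``theta_``, ``delta_``, ``loglik_``, ``aic_``,
    ``bic_``, ``se_``, ``cov_params_``, ``converged_``, ``result_``.
    """

    def __init__(
        self,
        *,
        free_xi1: bool = True,
        free_xi2: bool = True,
        free_beta2: bool = True,
        free_omega2: bool = True,
        mixed: bool = True,
        d0: float = D0_DEFAULT,
        tol: float = 1e-8,
        max_iter: int = 2000,
        n_restarts: int = 5,
        compute_se: bool = True,
        init: dict | None = None,
        random_state: int = 0,
    ):
        self.free_xi1 = free_xi1
        self.free_xi2 = free_xi2
        self.free_beta2 = free_beta2
        self.free_omega2 = free_omega2
        self.mixed = mixed
        self.d0 = d0
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.compute_se = compute_se
        self.init = init
        self.random_state = random_state

    # -- data plumbing ---------------------------------------------------

    @property
    def spec(self) -> ModelSpec:
        return ModelSpec(
            free_xi1=self.free_xi1,
            free_xi2=self.free_xi2,
            free_beta2=self.free_beta2,
            free_omega2=self.free_omega2,
            mixed=self.mixed,
        )

    @staticmethod
    def _coerce_design(X):
        """Return (animal labels, day array, dose array) from X."""
        if isinstance(X, pd.DataFrame):
            need = {"animal_id", "day", "dose_gy"}
            if not need.issubset(X.columns):
                raise ValueError(
                    f"X needs columns {sorted(need)}, got {list(X.columns)}"
                )
            return (
                X["animal_id"].astype(str).to_numpy(),
                X["day"].to_numpy(dtype=float),
                X["dose_gy"].to_numpy(dtype=float),
            )
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError(
                "array X must be (n, 3) with columns (animal, day, dose)"
            )
        return X[:, 0], X[:, 1], X[:, 2]

    # -- parameter packing ----------------------------------------------

    def _pack(self, values: dict, names) -> np.ndarray:
        z = []
        for n in names:
            v = values[n]
            if n in _LOG_SCALE:
                z.append(np.log(max(v, _VAR_FLOOR)))
            else:
                z.append(v)
        return np.array(z, dtype=float)

    def _unpack(self, z: np.ndarray, names) -> dict:
        out = {}
        for n, v in zip(names, z):
            out[n] = float(np.exp(v)) if n in _LOG_SCALE else float(v)
        return out

    def _theta_delta(self, values: dict) -> tuple[FixedEffects, VarianceComponents]:
        kw = {n: 0.0 for n in FIXED_NAMES}
        kw.update({n: values[n] for n in self.spec.free_fixed})
        theta = FixedEffects(**kw, d0=self.d0)
        if self.spec.mixed:
            delta = VarianceComponents(
                values["psi2"], values["phi2"], values["sigma2"]
            )
        else:
            delta = VarianceComponents(0.0, 0.0, values["sigma2"])
        return theta, delta

    # -- initialisation --------------------------------------------------

    def _default_init(self, animal, day, dose, y) -> dict:
        pre = day < 0
        xi0 = float(np.mean(y[pre])) if pre.any() else float(np.mean(y))
        # initial-decrease slope from day-0 drops regressed through the
        # origin on dose
        beta1 = 0.05
        num = den = 0.0
        for a in np.unique(animal):
            sel = animal == a
            d_a = float(dose[sel][0])
            if d_a <= 0:
                continue
            at0 = sel & (day == 0)
            pre_a = sel & pre
            if at0.any() and pre_a.any():
                drop = float(np.mean(y[pre_a]) - np.mean(y[at0]))
                num += drop * d_a
                den += d_a * d_a
        if den > 0:
            beta1 = num / den
        values = {
            "xi0": xi0, "xi1": 0.0, "xi2": 0.0,
            "beta1": beta1, "beta2": 0.0, "omega1": 1.0, "omega2": 0.0,
        }
        theta, _ = self._theta_delta({**values, "psi2": 0, "phi2": 0, "sigma2": 1})
        resid = y - mean_activity(day, dose, theta)
        # method-of-moments split of the residual variance
        df = pd.DataFrame({"a": animal, "d": day, "r": resid})
        a_mean = df.groupby("a")["r"].transform("mean").to_numpy()
        d_mean = df.groupby("d")["r"].transform("mean").to_numpy()
        g = resid.mean()
        inter = resid - a_mean - d_mean + g
        values["psi2"] = max(float(np.var(a_mean)), 1e-6)
        values["phi2"] = max(float(np.var(d_mean)), 1e-6)
        if self.spec.mixed:
            values["sigma2"] = max(float(np.var(inter)), 1e-6)
        else:
            values["sigma2"] = max(float(np.var(resid)), 1e-6)
        if self.init:
            values.update({k: float(v) for k, v in self.init.items()})
        return values

    # -- fitting ---------------------------------------------------------

    def fit(self, X, y):
        animal, day, dose = self._coerce_design(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != len(day):
            raise ValueError(f"X has {len(day)} rows but y has {len(y)}")
        if not np.all(np.isfinite(y)):
            raise ValueError("y contains non-finite values")
        if not np.all(np.isfinite(day)) or not np.all(np.isfinite(dose)):
            raise ValueError("X contains non-finite values")
        if np.any(dose < 0):
            raise ValueError("doses must be non-negative")
        if len(np.unique(dose)) < 2:
            raise ValueError(
                "singular design: the initial-decrease parameters need at "
                "least two distinct dose groups"
            )
        spec = self.spec
        a_codes, animals = pd.factorize(pd.Series(animal), sort=True)
        d_codes, days = pd.factorize(pd.Series(day), sort=True)
        self.animals_ = np.asarray(animals)
        self.days_ = np.asarray(days, dtype=float)

        names = list(spec.free_fixed) + list(spec.variance_names)
        init_values = self._default_init(np.asarray(animal), day, dose, y)
        z0 = self._pack(init_values, names)

        day_v, dose_v, y_v = day, dose, y
        cache = {}

        def negloglik(z):
            values = self._unpack(z, names)
            try:
                theta, delta = self._theta_delta(values)
                resid = y_v - mean_activity(day_v, dose_v, theta)
                ll = loglik_residuals(resid, a_codes, d_codes, delta)
            except (ValueError, FloatingPointError):
                return 1e12
            if not np.isfinite(ll):
                return 1e12
            return -ll

        bounds = []
        for n in names:
            if n == "omega1":
                bounds.append((-12.0, 12.0))
            elif n in VARIANCE_NAMES:
                bounds.append((-35.0, 8.0))
            else:
                bounds.append((None, None))

        rng = np.random.default_rng(self.random_state)
        best = None
        converged = False
        z_start = z0
        for attempt in range(self.n_restarts + 1):
            res = optimize.minimize(
                negloglik,
                z_start,
                method="L-BFGS-B",
                bounds=bounds,
                options={
                    "maxiter": self.max_iter,
                    "ftol": self.tol * 1e-4,
                    "gtol": 1e-7,
                },
            )
            if best is None or res.fun < best.fun:
                best = res
            if res.success and np.isfinite(res.fun):
                converged = True
                best = res if res.fun <= best.fun else best
                break
            z_start = z0 + rng.normal(scale=0.3, size=len(z0))
        assert best is not None

        values = self._unpack(best.x, names)
        theta, delta = self._theta_delta(values)
        loglik = -float(best.fun)
        k = spec.k_params
        n = len(y)

        self.free_names_ = tuple(names)
        self.theta_ = theta
        self.delta_ = delta
        self.loglik_ = loglik
        self.aic_ = -2.0 * loglik + 2.0 * k
        self.bic_ = -2.0 * loglik + k * np.log(n)
        self.n_obs_ = n
        self.k_params_ = k
        self.converged_ = converged
        self.n_iter_ = int(best.nit)

        se, cov = {}, None
        if self.compute_se:
            se, cov = self._se_and_cov(negloglik, best.x, names, values)
        self.se_ = se
        self.cov_params_ = cov

        self.result_ = FitResult(
            spec=spec,
            theta=theta,
            delta=delta,
            loglik=loglik,
            aic=self.aic_,
            bic=self.bic_,
            n_obs=n,
            k_params=k,
            converged=converged,
            se=se,
            cov_params=cov,
            n_iter=self.n_iter_,
            message=str(best.message),
        )
        return self

    def _se_and_cov(self, negloglik, z_opt, names, values):
        """Observed-information covariance, mapped to the natural scale.

        The information is differentiated in the optimisation coordinates
        (log scale for positivity-constrained parameters) and the
        covariance transformed back with the Jacobian of the
        reparameterisation.
        """
        try:
            with np.errstate(all="ignore"):
                info = -approx_hess(np.asarray(z_opt, dtype=float),
                                    lambda z: -negloglik(z))
            if not np.all(np.isfinite(info)):
                raise np.linalg.LinAlgError("non-finite information matrix")
            try:
                cov_z = np.linalg.inv(info)
            except np.linalg.LinAlgError:
                cov_z = np.linalg.pinv(info)
            jac = np.array(
                [values[n] if n in _LOG_SCALE else 1.0 for n in names]
            )
            cov_nat = cov_z * np.outer(jac, jac)
            diag = np.diag(cov_nat)
            se = {
                n: float(np.sqrt(v)) if v > 0 else np.nan
                for n, v in zip(names, diag)
            }
            if any(not np.isfinite(s) for s in se.values()):
                warnings.warn(
                    "observed information is singular or indefinite; some "
                    "standard errors are reported as missing"
                )
            cov = pd.DataFrame(cov_nat, index=list(names), columns=list(names))
            return se, cov
        except (np.linalg.LinAlgError, ValueError) as exc:
            warnings.warn(f"standard errors unavailable: {exc}")
            return {n: np.nan for n in names}, None

    def predict(self, X):
        """Expected log10 activity for the (animal, day, dose) rows of X."""
        check_is_fitted(self, "theta_")
        _, day, dose = self._coerce_design(X)
        return mean_activity(day, dose, self.theta_)


# -- panel-frame wrappers ------------------------------------------------


def fit(panel: pd.DataFrame, spec: ModelSpec = FULL_NLMM,
        init: dict | None = None, **options) -> FitResult:
    """Maximum-likelihood fit of a model spec to an activity panel."""
    panel = validate_panel(panel)
    est = ActivityNLMM(
        free_xi1=spec.free_xi1,
        free_xi2=spec.free_xi2,
        free_beta2=spec.free_beta2,
        free_omega2=spec.free_omega2,
        mixed=spec.mixed,
        init=init,
        **options,
    )
    est.fit(panel[["animal_id", "day", "dose_gy"]], panel["log_activity"])
    return est.result_


def standard_errors(result: FitResult) -> dict:
    """Per-parameter standard errors of a fit (NaN where unavailable)."""
    return dict(result.se)


@dataclass
class ModelSelection:
    """Outcome of AIC-based model selection over candidate specs."""

    best: FitResult
    table: pd.DataFrame
    fits: dict


def select_model(panel: pd.DataFrame, specs=None, mixed: bool = True,
                 **options) -> ModelSelection:
    """Fit candidate specs and pick the smallest-AIC converged fit.

    By default the candidates are all 16 togglings of
    {xi1, xi2, beta2, omega2} for the given ``mixed`` flag.  Ties are
    broken by fewer parameters, then lexicographic spec label.  Fits that
    fail to converge are excluded with a warning.
    """
    panel = validate_panel(panel)
    if specs is None:
        specs = ModelSpec.all_candidates(mixed=mixed)
    options.setdefault("compute_se", False)
    fits, rows = {}, []
    fitted: list[tuple[ModelSpec, FitResult]] = []
    # fit smaller models first so larger ones can be warm-started from any
    # nested solution that beats their own optimum (guarantees the nested
    # log-likelihood ordering up to optimizer tolerance)
    specs = sorted(specs, key=lambda s: (s.k_params, s.label))
    for spec in specs:
        result = fit(panel, spec, **options)
        free = set(spec.free_fixed)
        nested = [
            r for s2, r in fitted
            if s2.mixed == spec.mixed and set(s2.free_fixed) <= free
        ]
        if nested:
            best_nested = max(nested, key=lambda r: r.loglik)
            if best_nested.loglik > result.loglik + 1e-9:
                warm = {n: best_nested.estimate(n)
                        for n in best_nested.param_names}
                retry = fit(panel, spec, init=warm, **options)
                if retry.loglik > result.loglik:
                    result = retry
        fitted.append((spec, result))
        fits[spec.label] = result
        rows.append(
            {
                "spec": spec.label,
                "loglik": result.loglik,
                "k": result.k_params,
                "aic": result.aic,
                "bic": result.bic,
                "converged": result.converged,
            }
        )
        if not result.converged:
            warnings.warn(f"candidate {spec.label} did not converge; excluded")
    table = (
        pd.DataFrame(rows)
        .sort_values(["aic", "k", "spec"], ignore_index=True)
    )
    usable = [f for f in fits.values() if f.converged]
    if not usable:
        raise RuntimeError("no candidate model converged")
    best = min(usable, key=lambda f: (f.aic, f.k_params, f.spec.label))
    return ModelSelection(best=best, table=table, fits=fits)
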