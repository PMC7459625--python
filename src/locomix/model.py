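"""Core model: mean function, crossed random-effects covariance, likelihood.

The observed quantity is the log10 nightly locomotor activity ``y_it`` of
animal ``i`` on day ``t`` (day 0 = day of irradiation, dose ``D_i`` in Gy).
The model is

.. math::

    y_{it} = f(t \\mid D_i, \\theta) + \\delta_i + \\eta_t + \\varepsilon_{it}

with mean function

.. math::

    f(t \\mid D, \\theta) = \\xi_0 + \\xi_1 t + \\xi_2 t^2
        - (\\beta_1 D + \\beta_2 D^2)\\,
          e^{-r(D)\\,t}\\, h(t), \\qquad
    r(D) = \\omega_1 e^{-\\omega_2 (D - D_0)}

where ``h`` is the Heaviside step (0 before irradiation, 1 from day 0 on)
and ``D_0`` is a fixed centering dose so that ``omega1`` is the recovery
rate *at* ``D_0`` and ``omega2`` its per-Gy modulation.  The three random
terms are independent zero-mean Gaussians: an animal effect
``delta_i ~ N(0, psi2)`` (stable individual differences), a day effect
``eta_t ~ N(0, phi2)`` shared by all animals on the same night (room
conditions), and a per-cell measurement error ``eps_it ~ N(0, sigma2)``.

Because the animal and day classifications are *crossed*, the stacked
vector of observations is multivariate normal with covariance

    Cov(y_{it}, y_{jt'}) = psi2 * 1{i=j} + phi2 * 1{t=t'}
                           + sigma2 * 1{i=j, t=t'}

which this module evaluates either densely (general, any pattern of
observed cells) or through the eigendecomposition of the balanced fully
crossed design (every animal observed on every day), where the covariance
is ``psi2 (I_a ⊗ J_d) + phi2 (J_a ⊗ I_d) + sigma2 I`` and the quadratic
form and determinant reduce to four orthogonal projections.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "D0_DEFAULT",
    "FixedEffects",
    "VarianceComponents",
    "ModelSpec",
    "FULL_NLMM",
    "OPTIMAL_NLMM",
    "FULL_NLRM",
    "OPTIMAL_NLRM",
    "heaviside",
    "recovery_rate",
    "mean_activity",
    "covariance_matrix",
    "log_likelihood",
    "q_objective",
    "params_to_dict",
    "params_from_dict",
]

D0_DEFAULT = 2.75
"""Default centering dose in Gy (midpoint-ish of the 0-5.5 Gy design range)."""

_LOG2PI = float(np.log(2.0 * np.pi))

#: Canonical ordering of the fixed-effect parameter names.
FIXED_NAMES = ("xi0", "xi1", "xi2", "beta1", "beta2", "omega1", "omega2")
VARIANCE_NAMES = ("psi2", "phi2", "sigma2")


@dataclass(frozen=True)
class FixedEffects:
    """Fixed-effect parameters theta of the activity model.

    Parameters fixed to zero by a submodel are simply set to 0 here; the
    mean function needs a complete vector.  ``d0`` is configuration
    (covariate centering), never estimated.
    """

    xi0: float
    xi1: float = 0.0
    xi2: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0
    omega1: float = 1.0
    omega2: float = 0.0
    d0: float = D0_DEFAULT

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def replace(self, **kw) -> "FixedEffects":
        return replace(self, **kw)


@dataclass(frozen=True)
class VarianceComponents:
    """Dispersion parameters Delta = (psi2, phi2, sigma2).

    All on the squared log10-activity scale.  ``psi2`` is the
    between-animal variance, ``phi2`` the between-day variance and
    ``sigma2`` the measurement-error variance.  Likelihood evaluation
    additionally requires ``sigma2 > 0`` (positive definiteness); a pure
    simulation may use zeros.
    """

    psi2: float
    phi2: float
    sigma2: float

    def __post_init__(self):
        bad = [n for n in VARIANCE_NAMES if getattr(self, n) < 0]
        if bad:
            raise ValueError(f"negative variance component(s): {', '.join(bad)}")

    @property
    def total(self) -> float:
        return self.psi2 + self.phi2 + self.sigma2

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def require_positive_definite(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError(
                "covariance is not positive definite: sigma2 must be > 0 "
                f"(got sigma2={self.sigma2})"
            )


@dataclass(frozen=True)
class ModelSpec:
    """Which optional parameters are free.

    ``xi0``, ``beta1``, ``omega1`` and ``sigma2`` are always estimated;
    the four flags toggle the optional fixed effects, and ``mixed``
    switches between the mixed model (animal/day random effects) and the
    ordinary non-linear regression limit ``psi2 = phi2 = 0``.
    """

    free_xi1: bool = True
    free_xi2: bool = True
    free_beta2: bool = True
    free_omega2: bool = True
    mixed: bool = True

    _OPTIONAL = ("xi1", "xi2", "beta2", "omega2")

    @property
    def free_fixed(self) -> tuple[str, ...]:
        """Names of free fixed effects, in canonical order."""
        return tuple(
            n
            for n in FIXED_NAMES
            if n in ("xi0", "beta1", "omega1") or getattr(self, f"free_{n}")
        )

    @property
    def n_fixed(self) -> int:
        return len(self.free_fixed)

    @property
    def k_params(self) -> int:
        """Total number of estimated parameters (fixed + variance)."""
        return self.n_fixed + (3 if self.mixed else 1)

    @property
    def variance_names(self) -> tuple[str, ...]:
        return VARIANCE_NAMES if self.mixed else ("sigma2",)

    @property
    def label(self) -> str:
        extra = [n for n in self._OPTIONAL if getattr(self, f"free_{n}")]
        body = "+".join(extra) if extra else "base"
        return ("NLMM:" if self.mixed else "NLRM:") + body

    def as_dict(self) -> dict:
        return {
            "free_xi1": self.free_xi1,
            "free_xi2": self.free_xi2,
            "free_beta2": self.free_beta2,
            "free_omega2": self.free_omega2,
            "mixed": self.mixed,
        }

    @classmethod
    def all_candidates(cls, mixed: bool = True) -> list["ModelSpec"]:
        """The 16 togglings of {xi1, xi2, beta2, omega2} for one mixed flag."""
        out = []
        for a in (True, False):
            for b in (True, False):
                for c in (True, False):
                    for d in (True, False):
                        out.append(
                            cls(free_xi1=a, free_xi2=b, free_beta2=c,
                                free_omega2=d, mixed=mixed)
                        )
        return out


FULL_NLMM = ModelSpec()
OPTIMAL_NLMM = ModelSpec(free_xi1=False, free_xi2=False, free_omega2=False)
FULL_NLRM = ModelSpec(mixed=False)
OPTIMAL_NLRM = ModelSpec(free_xi1=False, free_beta2=False, free_omega2=False,
                         mixed=False)


def heaviside(t):
    """Pre/post-irradiation indicator: 0 for t < 0, 1 for t >= 0."""
    return np.where(np.asarray(t, dtype=float) >= 0, 1.0, 0.0)


def recovery_rate(dose, theta: FixedEffects):
    """Recovery rate r(D) = omega1 * exp(-omega2 * (D - D0)), per day."""
    dose = np.asarray(dose, dtype=float)
    expo = np.clip(-theta.omega2 * (dose - theta.d0), -700.0, 700.0)
    return theta.omega1 * np.exp(expo)


def mean_activity(t, dose, theta: FixedEffects):
    """Expected log10 activity f(t | D, theta).

    Vectorised over ``t`` and ``dose`` (broadcast together).  ``t`` is a
    real covariate, so fitted trend curves can be evaluated on a fine
    grid even though the study design observes integer days.
    """
    t = np.asarray(t, dtype=float)
    dose = np.asarray(dose, dtype=float)
    baseline = theta.xi0 + theta.xi1 * t + theta.xi2 * t * t
    r = recovery_rate(dose, theta)
    # decay only matters on t >= 0 where h(t) = 1; clamp the exponent so a
    # wandering optimizer cannot overflow
    t_pos = np.maximum(t, 0.0)
    decay = np.exp(np.clip(-r * t_pos, -745.0, 0.0))
    drop = (theta.beta1 * dose + theta.beta2 * dose * dose) * decay * heaviside(t)
    return baseline - drop


def _cell_codes(panel: pd.DataFrame):
    """Integer animal/day codes for the rows of a panel, canonical order."""
    a_codes, animals = pd.factorize(panel["animal_id"], sort=True)
    d_codes, days = pd.factorize(panel["day"], sort=True)
    return a_codes, animals, d_codes, days


def covariance_matrix(animal_idx, day_idx, delta: VarianceComponents) -> np.ndarray:
    """Dense covariance of the stacked observations over the given cells.

    ``animal_idx`` and ``day_idx`` give, per observation, which animal and
    which day the cell belongs to.  Entry for cells (i,t),(j,t') is
    ``psi2*1{i=j} + phi2*1{t=t'} + sigma2*1{i=j and t=t'}``.  Works for any
    (unbalanced) pattern of observed cells.
    """
    animal_idx = np.asarray(animal_idx)
    day_idx = np.asarray(day_idx)
    same_animal = animal_idx[:, None] == animal_idx[None, :]
    same_day = day_idx[:, None] == day_idx[None, :]
    omega = delta.psi2 * same_animal + delta.phi2 * same_day
    omega[np.diag_indices_from(omega)] += delta.sigma2
    return omega


def _is_balanced(animal_idx, day_idx, n_animals: int, n_days: int) -> bool:
    if len(animal_idx) != n_animals * n_days:
        return False
    occupancy = np.bincount(
        animal_idx * n_days + day_idx, minlength=n_animals * n_days
    )
    return bool(np.all(occupancy == 1))


def _loglik_dense(resid, animal_idx, day_idx, delta: VarianceComponents) -> float:
    omega = covariance_matrix(animal_idx, day_idx, delta)
    try:
        cf = linalg.cho_factor(omega, lower=True)
    except linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        raise ValueError(
            f"covariance not positive definite for psi2={delta.psi2}, "
            f"phi2={delta.phi2}, sigma2={delta.sigma2}"
        ) from exc
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    quad = float(resid @ linalg.cho_solve(cf, resid))
    n = len(resid)
    return -0.5 * (n * _LOG2PI + logdet + quad)


def _loglik_balanced(resid_mat: np.ndarray, delta: VarianceComponents) -> float:
    """Exact log-likelihood on a fully crossed design via eigenstructure.

    On the balanced a x d grid the covariance has four eigenspaces: the
    grand mean, animal contrasts averaged over days, day contrasts
    averaged over animals, and the interaction space, with eigenvalues
    sigma2 + d*psi2 + a*phi2, sigma2 + d*psi2, sigma2 + a*phi2 and sigma2.
    O(n) instead of a dense Cholesky; validated against the dense path in
    the test suite.
    """
    a, d = resid_mat.shape
    psi2, phi2, sigma2 = delta.psi2, delta.phi2, delta.sigma2
    grand = resid_mat.mean()
    row_dev = resid_mat.mean(axis=1) - grand
    col_dev = resid_mat.mean(axis=0) - grand
    ss_total = float(np.sum(resid_mat * resid_mat))
    ss_grand = a * d * grand * grand
    ss_row = d * float(np.sum(row_dev * row_dev))
    ss_col = a * float(np.sum(col_dev * col_dev))
    ss_resid = max(ss_total - ss_grand - ss_row - ss_col, 0.0)

    lam_grand = sigma2 + d * psi2 + a * phi2
    lam_row = sigma2 + d * psi2
    lam_col = sigma2 + a * phi2
    lam_resid = sigma2
    logdet = (
        np.log(lam_grand)
        + (a - 1) * np.log(lam_row)
        + (d - 1) * np.log(lam_col)
        + (a - 1) * (d - 1) * np.log(lam_resid)
    )
    quad = (
        ss_grand / lam_grand
        + ss_row / lam_row
        + ss_col / lam_col
        + ss_resid / lam_resid
    )
    return -0.5 * (a * d * _LOG2PI + logdet + quad)


def loglik_residuals(resid, animal_idx, day_idx, delta: VarianceComponents,
                     method: str = "auto") -> float:
    """Gaussian log-likelihood of residuals under the crossed covariance.

    ``method`` is ``"auto"`` (balanced eigen path when the design is fully
    crossed, diagonal closed form when psi2 = phi2 = 0, dense Cholesky
    otherwise), ``"dense"`` or ``"balanced"``.
    """
    delta.require_positive_definite()
    resid = np.asarray(resid, dtype=float)
    animal_idx = np.asarray(animal_idx)
    day_idx = np.asarray(day_idx)
    n_animals = int(animal_idx.max()) + 1 if len(animal_idx) else 0
    n_days = int(day_idx.max()) + 1 if len(day_idx) else 0

    if method == "dense":
        return _loglik_dense(resid, animal_idx, day_idx, delta)

    if delta.psi2 == 0.0 and delta.phi2 == 0.0 and method == "auto":
        n = len(resid)
        rss = float(resid @ resid)
        return -0.5 * (n * _LOG2PI + n * np.log(delta.sigma2) + rss / delta.sigma2)

    balanced = _is_balanced(animal_idx, day_idx, n_animals, n_days)
    if method == "balanced" and not balanced:
        raise ValueError("balanced method requested on an unbalanced design")
    if balanced:
        order = np.lexsort((day_idx, animal_idx))
        mat = resid[order].reshape(n_animals, n_days)
        return _loglik_balanced(mat, delta)
    return _loglik_dense(resid, animal_idx, day_idx, delta)


def log_likelihood(panel: pd.DataFrame, theta: FixedEffects,
                   delta: VarianceComponents, method: str = "auto") -> float:
    """Exact multivariate-normal log-likelihood of an activity panel.

    ``panel`` needs columns ``animal_id``, ``dose_gy``, ``day``,
    ``log_activity``.  The normalisation constant is the standard
    ``(2*pi)^(n/2)`` with n = number of panel rows.
    """
    resid = panel["log_activity"].to_numpy(dtype=float) - mean_activity(
        panel["day"].to_numpy(), panel["dose_gy"].to_numpy(), theta
    )
    a_codes, _, d_codes, _ = _cell_codes(panel)
    return loglik_residuals(resid, a_codes, d_codes, delta, method=method)


def q_objective(panel: pd.DataFrame, theta: FixedEffects,
                delta: VarianceComponents, method: str = "auto") -> float:
    """Minimisation objective Q = -2 * log-likelihood.

    On a diagonal covariance (psi2 = phi2 = 0) this reduces to
    ``n log(2 pi) + n log(sigma2) + RSS / sigma2``.
    """
    return -2.0 * log_likelihood(panel, theta, delta, method=method)


def params_to_dict(theta: FixedEffects, delta: VarianceComponents | None = None
                   ) -> dict[str, float]:
    """Flat serialisable parameter dictionary (keys xi0..omega2, D0, psi2..)."""
    out = {n: getattr(theta, n) for n in FIXED_NAMES}
    out["D0"] = theta.d0
    if delta is not None:
        out.update({n: getattr(delta, n) for n in VARIANCE_NAMES})
    return out


def params_from_dict(d: dict) -> tuple[FixedEffects, VarianceComponents | None]:
    """Inverse of :func:`params_to_dict`."""
    theta = FixedEffects(
        **{n: float(d.get(n, 0.0)) for n in FIXED_NAMES},
        d0=float(d.get("D0", D0_DEFAULT)),
    )
    if all(n in d for n in VARIANCE_NAMES):
        delta = VarianceComponents(*(float(d[n]) for n in VARIANCE_NAMES))
    else:
        delta = None
    return theta, delta
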