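"""Model-exact synthetic data with known ground truth.

The study this package models observed 16 male Wistar rats (4 dose
groups: 0, 2.0, 3.5 and 5.0 Gy of whole-body gamma irradiation, 4 rats
per group) over 24 nights, days -3..20 relative to irradiation.  The
defaults of :class:`SimulationDesign` reproduce that design, with the
fixed effects and variance components set to the point estimates reported
for the optimal mixed model of the original analysis
(``REFERENCE_THETA``/``REFERENCE_DELTA``), so simulated panels are drawn
from the model at the published operating point.

Two generators are provided: :func:`simulate_panel` draws log-activity
panels exactly from the model (the cell identity
``y = f + delta_i + eta_t + eps_it`` holds by construction and is
returned as ground truth), and :func:`simulate_raw_counts` emits
minute-resolution movement counts from a two-rate (day/night)
inhomogeneous Poisson process whose expected nightly totals match the
panel, so the ingest pipeline can be exercised end to end.
:func:`recovery_experiment` is the standard simulate-refit harness
reporting bias, RMSE and CI coverage.

Randomness: a single root seed is split into independent child streams
(animal effects, day effects, errors, raw counts) so enlarging one part
of a simulation never reshuffles another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .estimator import ActivityNLMM, FitResult, fit as _fit
from .model import (
    OPTIMAL_NLMM,
    FixedEffects,
    ModelSpec,
    VarianceComponents,
    mean_activity,
)
from .panel import MovementCountSeries, validate_panel

__all__ = [
    "REFERENCE_THETA",
    "REFERENCE_DELTA",
    "SimulationDesign",
    "SimulatedTruth",
    "simulate_panel",
    "simulate_raw_counts",
    "RecoveryResult",
    "recovery_experiment",
]

#: Optimal-mixed-model point estimates from the original rat study,
#: used as the default generating truth.
REFERENCE_THETA = FixedEffects(
    xi0=4.319, beta1=0.066, beta2=-0.006, omega1=9.063
)
REFERENCE_DELTA = VarianceComponents(psi2=0.0018, phi2=0.0019, sigma2=0.0015)


@dataclass(frozen=True)
class SimulationDesign:
    """Design of a simulated activity experiment.

    Defaults reproduce the study conditions: 4 animals in each of 4 dose
    groups (0, 2.0, 3.5, 5.0 Gy) observed on days -3..20, generated at
    the reference parameter values.
    """

    n_per_group: int = 4
    doses: tuple = (0.0, 2.0, 3.5, 5.0)
    days: tuple = tuple(range(-3, 21))
    theta: FixedEffects = REFERENCE_THETA
    delta: VarianceComponents = REFERENCE_DELTA
    seed: int = 0

    @property
    def n_animals(self) -> int:
        return self.n_per_group * len(self.doses)

    @property
    def animal_ids(self) -> list[str]:
        width = max(2, len(str(self.n_animals)))
        return [f"R{i + 1:0{width}d}" for i in range(self.n_animals)]

    @property
    def dose_by_animal(self) -> dict[str, float]:
        ids = self.animal_ids
        return {
            ids[g * self.n_per_group + j]: float(d)
            for g, d in enumerate(self.doses)
            for j in range(self.n_per_group)
        }


@dataclass
class SimulatedTruth:
    """A simulated panel together with every random draw that produced it."""

    panel: pd.DataFrame
    delta_true: pd.DataFrame  # animal_id, dose_gy, delta
    eta_true: pd.DataFrame  # day, eta
    eps_true: pd.DataFrame  # animal_id, day, eps
    design: SimulationDesign

    def cell_identity_error(self) -> float:
        """Max abs deviation of y - f - delta - eta - eps (0 by construction)."""
        p = self.panel
        f = mean_activity(p["day"].to_numpy(), p["dose_gy"].to_numpy(),
                          self.design.theta)
        d = self.delta_true.set_index("animal_id")["delta"]
        e = self.eta_true.set_index("day")["eta"]
        eps = self.eps_true.set_index(["animal_id", "day"])["eps"]
        recon = (
            f
            + d.loc[p["animal_id"]].to_numpy()
            + e.loc[p["day"]].to_numpy()
            + eps.loc[list(zip(p["animal_id"], p["day"]))].to_numpy()
        )
        return float(np.max(np.abs(p["log_activity"].to_numpy() - recon)))


def _streams(seed: int, n: int = 4):
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def simulate_panel(design: SimulationDesign) -> SimulatedTruth:
    """Draw one activity panel exactly from the model.

    Animal effects, day effects and errors are independent zero-mean
    normals with variances (psi2, phi2, sigma2); the observation is
    assembled by the cell identity.  Reproducible from ``design.seed``.
    """
    rng_animal, rng_day, rng_eps, _ = _streams(design.seed)
    ids = design.animal_ids
    dose_map = design.dose_by_animal
    days = np.asarray(design.days, dtype=int)
    n_a, n_d = len(ids), len(days)

    d = design.delta
    delta_i = rng_animal.normal(0.0, np.sqrt(d.psi2), size=n_a)
    eta_t = rng_day.normal(0.0, np.sqrt(d.phi2), size=n_d)
    eps = rng_eps.normal(0.0, np.sqrt(d.sigma2), size=(n_a, n_d))

    rows = []
    for i, a in enumerate(ids):
        dose = dose_map[a]
        f = mean_activity(days, np.full(n_d, dose), design.theta)
        y = f + delta_i[i] + eta_t + eps[i]
        for j, t in enumerate(days):
            rows.append((a, dose, int(t), float(y[j])))
    panel = validate_panel(
        pd.DataFrame(rows, columns=["animal_id", "dose_gy", "day",
                                    "log_activity"])
    )
    delta_true = pd.DataFrame(
        {"animal_id": ids, "dose_gy": [dose_map[a] for a in ids],
         "delta": delta_i}
    )
    eta_true = pd.DataFrame({"day": days, "eta": eta_t})
    eps_true = pd.DataFrame(
        {
            "animal_id": np.repeat(ids, n_d),
            "day": np.tile(days, n_a),
            "eps": eps.ravel(),
        }
    )
    return SimulatedTruth(panel, delta_true, eta_true, eps_true, design)


def simulate_raw_counts(
    truth: SimulatedTruth,
    day_night_ratio: float = 0.3,
    irradiation_date: str = "2014-05-01",
    night_start_hour: int = 18,
    night_end_hour: int = 6,
    seed: int | None = None,
) -> list[MovementCountSeries]:
    """Minute-resolution Poisson counts whose nightly totals match the panel.

    For each animal-night the per-minute night rate is chosen so the
    expected total over the 720-minute window equals ``10^log_activity``;
    daytime minutes use ``day_night_ratio`` times the adjacent night's
    rate, giving the characteristic steeper nocturnal slope of cumulative
    movement curves.  Feeding the result through the ingest pipeline
    recovers the panel's log activities up to Poisson counting noise.
    """
    if day_night_ratio <= 0:
        raise ValueError(f"day/night rate ratio must be > 0, got {day_night_ratio}")
    if seed is None:
        _, _, _, rng = _streams(truth.design.seed)
    else:
        rng = np.random.default_rng(seed)
    night_minutes = ((24 - night_start_hour) + night_end_hour) * 60
    base = pd.Timestamp(irradiation_date)
    panel = truth.panel
    series = []
    for animal, grp in panel.groupby("animal_id", sort=True):
        targets = grp.set_index("day")["log_activity"].to_dict()
        expected = {t: 10.0 ** v for t, v in targets.items()}
        too_low = [t for t, v in expected.items() if v < 1.0]
        if too_low:
            raise ValueError(
                f"animal {animal}: target log activity implies < 1 expected "
                f"count per night on day(s) {too_low}"
            )
        t_min = min(targets)
        t_max = max(targets)
        start = base + pd.Timedelta(days=t_min, hours=night_end_hour)
        end = base + pd.Timedelta(days=t_max + 1, hours=night_end_hour)
        stamps = pd.date_range(start, end, freq="1min", inclusive="left")
        hours = stamps.hour
        in_night = (hours >= night_start_hour) | (hours < night_end_hour)
        # day offset of the night each minute belongs to (or is adjacent to)
        night_day = np.where(
            hours >= night_end_hour,
            (stamps - base).days,
            (stamps - base).days - 1,
        )
        # daytime minutes precede that date's night; clamp to observed range
        night_day = np.clip(night_day, t_min, t_max)
        night_rate = np.array([expected[int(t)] / night_minutes
                               for t in night_day])
        rates = np.where(in_night, night_rate, day_night_ratio * night_rate)
        counts = rng.poisson(rates)
        series.append(
            MovementCountSeries(
                animal_id=str(animal), timestamps=stamps, counts=counts
            )
        )
    return series


@dataclass
class RecoveryResult:
    """Aggregate of a simulate-refit experiment."""

    summary: pd.DataFrame
    estimates: pd.DataFrame
    n_requested: int
    n_converged: int

    @property
    def n_excluded(self) -> int:
        return self.n_requested - self.n_converged


def recovery_experiment(
    design: SimulationDesign,
    n_replicates: int,
    seed: int = 0,
    spec: ModelSpec = OPTIMAL_NLMM,
    compute_se: bool = True,
    ci_level: float = 0.95,
) -> RecoveryResult:
    """Simulate-and-refit harness: bias, RMSE and CI coverage per parameter.

    Each replicate draws a fresh panel from ``design`` (replicate seeds
    derived from ``seed``), fits ``spec`` by maximum likelihood and
    records the estimates.  Replicates whose fit does not converge are
    excluded and counted.  Coverage is reported for fixed effects with an
    available standard error.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    rep_seeds = (
        np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    )
    names = list(spec.free_fixed) + list(spec.variance_names)
    truth_vals = {
        n: getattr(design.theta, n, None)
        if n in spec.free_fixed
        else getattr(design.delta, n)
        for n in names
    }
    records, covered = [], {n: [] for n in spec.free_fixed}
    n_converged = 0
    from scipy import stats as _st

    z = _st.norm.ppf(0.5 + ci_level / 2.0)
    for r, s in enumerate(rep_seeds):
        truth = simulate_panel(replace(design, seed=int(s)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = _fit(truth.panel, spec, compute_se=compute_se)
        if not result.converged:
            continue
        n_converged += 1
        rec = {"replicate": r}
        for n in names:
            rec[n] = result.estimate(n)
        records.append(rec)
        if compute_se:
            for n in spec.free_fixed:
                se = result.se.get(n, np.nan)
                if np.isfinite(se) and se > 0:
                    est = result.estimate(n)
                    covered[n].append(
                        abs(est - truth_vals[n]) <= z * se
                    )
    if not records:
        raise RuntimeError("no replicate converged")
    estimates = pd.DataFrame(records)
    rows = []
    m = len(estimates)
    for n in names:
        vals = estimates[n].to_numpy()
        truth_v = truth_vals[n]
        bias = float(vals.mean() - truth_v)
        sd = float(vals.std(ddof=1))
        rows.append(
            {
                "parameter": n,
                "truth": truth_v,
                "mean": float(vals.mean()),
                "bias": bias,
                "sd": sd,
                "mc_se": sd / np.sqrt(m),
                "rmse": float(np.sqrt(np.mean((vals - truth_v) ** 2))),
                "coverage": (
                    float(np.mean(covered[n])) if covered.get(n) else np.nan
                ),
            }
        )
    summary = pd.DataFrame(rows).set_index("parameter")
    return RecoveryResult(
        summary=summary,
        estimates=estimates,
        n_requested=n_replicates,
        n_converged=n_converged,
    )
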