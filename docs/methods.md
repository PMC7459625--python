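# Methods

This note documents the statistical model, the numerical choices, and
the synthetic-data generator behind `locomix`, including the design
decisions that were genuinely open and the limitations a user should
know about.

## Data reduction

Raw input is one movement count per animal per minute from an infrared
sensor. Because rats are nocturnal, the analysis unit is the **nightly
total**: the sum of counts in the half-open window [18:00, 06:00), a
night being labelled by the calendar date on which it starts. The
half-open convention resolves the boundary minute unambiguously (the
06:00 interval belongs to daytime). Nights with any missing interval
are flagged and excluded from the panel rather than rescaled — there is
no defensible rescaling rule without a model of why intervals are
missing, and partial-night sums would bias the log scale downward.

Totals are transformed with **log base 10**. On this scale a typical
untreated night of ~20,000 movements gives values near 4.3, and dose
effects of 0.05–0.2 log10 units correspond to activity ratios of
0.89–0.63. Zero totals cannot be log-transformed and are an explicit
error: the caller decides whether to drop or impute such nights.

The analysis panel is one row per (animal, day) with the animal's dose
and the day index relative to irradiation (day 0 = the night starting
on the irradiation date). Panel validation enforces unique cells, a
single dose per animal, and finite values; days need not be contiguous
(the likelihood supports unbalanced panels).

## Model

With `y_it` the log10 activity of animal `i` at day `t`:

```
y_it = f(t | D_i, θ) + δ_i + η_t + ε_it
f(t|D,θ) = ξ0 + ξ1 t + ξ2 t² − (β1 D + β2 D²)·exp(−r(D)·t)·h(t)
r(D) = ω1 · exp(−ω2 (D − D0))
```

`δ_i ~ N(0, ψ²)` is a stable animal effect, `η_t ~ N(0, φ²)` a night
effect shared by all animals (housing-room conditions), and
`ε_it ~ N(0, σ²)` measurement error; all independent. `D0` is a fixed
centering constant (default 2.75 Gy) so that `ω1` is the recovery rate
at `D0` and `ω2` its per-Gy log-modulation; it is configuration, never
estimated. `t` is treated as a real covariate so fitted curves can be
drawn on a fine grid, although the design observes integer days.

Because animal and day classifications are **crossed**, the stacked
vector is multivariate normal with covariance

```
Cov(y_it, y_jt') = ψ²·1{i=j} + φ²·1{t=t'} + σ²·1{i=j, t=t'}
```

This entrywise rule is implemented directly from the random-effects
decomposition; it is the unambiguous consequence of the model equation
and covers unbalanced panels by restriction to observed cells. On a
balanced fully crossed a × d design it is equivalent to the Kronecker
form `ψ²(I_a ⊗ J_d) + φ²(J_a ⊗ I_d) + σ² I` (asserted in the tests).

## Likelihood and optimisation

The log-likelihood is the exact Gaussian log density with the standard
`(2π)^(n/2)` normalisation, `n` the number of panel rows. Two
evaluation paths exist:

- **dense** — Cholesky factorisation of the n × n covariance; general,
  used for unbalanced panels and as the reference in tests;
- **balanced** — on a fully crossed design the covariance has four
  eigenspaces (grand mean; animal contrasts averaged over days; day
  contrasts averaged over animals; interaction) with eigenvalues
  `σ² + dψ² + aφ²`, `σ² + dψ²`, `σ² + aφ²`, `σ²`, so the determinant
  and quadratic form reduce to four projection sums in O(n). The two
  paths agree to machine precision; the balanced path is what makes
  200-replicate simulation studies take seconds rather than hours.

Estimation is **direct maximum likelihood** (not REML): ML is required
for AIC comparison across fixed-effect structures. L-BFGS-B minimises
−2·loglik over the free parameters; `ω1`, `ψ²`, `φ²`, `σ²` are
optimised on the log scale (positivity) and reported on the natural
scale, with wide box bounds on the log coordinates (±12 for log ω1,
[−35, 8] for log variances) purely as overflow guards. Convergence
tolerance is 1e-8 on the objective, at most 2000 iterations, and up to
5 jittered restarts (fixed seed) if the first attempt fails.

Initialisation is data-driven: `ξ0` from the pre-irradiation mean,
`β1` from the day-0 group-mean drops regressed through the origin on
dose, `ω1 = 1`, other fixed effects 0, variance components from a
method-of-moments (row/column/interaction means) split of the initial
residuals.

Standard errors come from the inverse of the numerically
differentiated observed information at the optimum. Differentiation is
done in the optimisation coordinates and the covariance mapped to the
natural scale with the Jacobian of the reparameterisation (equivalent
to differentiating on the natural scale, but robust when a variance
component sits near zero). Variance-component SEs are reported but are
rough — the usual caveat that Wald theory is poor for variances near a
boundary applies. A singular information matrix (e.g. a flat `ω1`
direction, see limitations) falls back to a pseudo-inverse and flags
affected SEs as missing.

## Inference conventions

- 95% Wald intervals `estimate ± 1.96·SE` (exact normal quantile).
- **p-values are one-sided**: `p = 1 − Φ(|estimate|/SE)`. This is
  deliberate and unconventional — it matches the convention of the
  reference analysis this package reproduces. Double the values for
  two-sided tests.
- AIC = −2·loglik + 2k, BIC = −2·loglik + k·log n, k counting free
  fixed effects plus variance components (3 if mixed, 1 otherwise).

Model selection fits all 16 togglings of `{ξ1, ξ2, β2, ω2}` for a given
mixed flag and picks the converged candidate with smallest AIC; ties go
to fewer parameters, then lexicographic label. Candidates are fitted
smallest-first and larger candidates are warm-started from any nested
solution that beats their own optimum, which enforces the nested
log-likelihood ordering up to optimizer tolerance.

## Random effects and diagnostics

Posterior means (BLUPs) are computed by joint-Gaussian conditioning,
`(δ̂, η̂) = G Z' Ω̂⁻¹ (y − μ̂)`, and the per-cell residual is *defined*
by the identity `ε̂_it = y_it − f̂ − δ̂_i − η̂_t`, which therefore holds
exactly. No sum-to-zero constraint is imposed on δ̂ or η̂; on balanced
designs they are near-zero-sum automatically up to shrinkage.

Variance shares are each component over the total, ×100; both exact and
nearest-integer display values are returned (rounding the inputs first
can differ by a point from rounding at the end).

The serial-independence check on the day effects is the Durbin–Watson
statistic `DW = Σ(η̂_t − η̂_{t−1})²/Ση̂_t²`. Since η̂ are shrunken
predictions, not regression residuals, the classical DW null tables do
not apply; the p-value is instead a **two-sided permutation tail**
(default 10,000 random reorderings, fixed seed): the fraction of
permutations whose DW is at least as far from 2 as observed, with the
standard +1 correction. This is a documented approximation, not a
classical DW test.

## Dose–response summaries

The initial decrease at dose D is `β̂1 D + β̂2 D²` with a delta-method
CI using gradient (D, D²) against the fitted (β1, β2) covariance; at
D = 0 it is identically zero. The recovery rate is `r(D)` above
(constant in D when ω2 is dropped). "Recovery time" has no canonical
definition; the package uses the time until the remaining decrease
falls to a fraction (default 5%) of its day-0 value, with closed form
`t* = −log(fraction)/r(D)`, and exposes the fraction as a parameter.
Per-animal observed day-0 drops from the fitted baseline are exported
for plotting only, never used in estimation.

## Synthetic data

The generator's default design **is** the study condition the package
targets: 16 animals, 4 per dose group at 0/2.0/3.5/5.0 Gy, days −3..20
(384 cells), with generating parameters fixed at the reference
operating point — the optimal-model estimates of the original rat
gamma-irradiation experiment: ξ0 = 4.319, β1 = 0.066, β2 = −0.006,
ω1 = 9.063 (ξ1 = ξ2 = ω2 = 0) and (ψ², φ², σ²) =
(0.0018, 0.0019, 0.0015). Panels are drawn *exactly* from the model, so
the cell identity holds by construction and every draw is returned as
ground truth. A single root seed is split into independent child
streams (animal effects, day effects, errors, raw counts), so enlarging
one part of a simulation never reshuffles another.

Raw circadian counts are emulated with a two-rate inhomogeneous Poisson
process: the per-minute night rate is set so the expected 720-minute
nightly total equals `10^y` for the panel's target `y`, and daytime
minutes run at a fixed fraction (default 0.3) of the adjacent night's
rate. This reproduces the qualitative shape of cumulative-movement
curves (steeper night segments) and round-trips through the ingest
pipeline to the generating panel up to Poisson noise (~0.003 in log10
at 20,000 counts). It does **not** model ultradian rhythm, sensor dead
time, overdispersion, or weight-dependent activity — passing tests
show the pipeline arithmetic is right, not that real sensors behave
like Poisson processes.

The simulate-and-refit harness (`recovery_experiment`) runs 200
replicates by default in the acceptance script; at that size the
Monte-Carlo SE of the mean σ̂² is ~8e-6, an order of magnitude below
the quantity itself, while a full run stays under a minute.

## Known limitations

- **ω1 is weakly identified at fast recovery.** At the reference truth
  (ω1 ≈ 9/day) the decrease term has decayed by ~e⁻⁹ at day 1, so only
  the day-0 cells inform the recovery rate and the likelihood is flat
  in ω1 above a few units per day. Point estimates of ω1 in
  simulations are heavy-tailed and its Wald SE can be enormous or
  missing; the quantities of scientific interest (β1, β2, σ², the
  day-0 decrease) are unaffected.
- Wald intervals and one-sided p-values are asymptotic; with 16
  animals the animal-level variance ψ² is estimated from 16 effective
  observations and its SE should not be over-read.
- The Durbin–Watson p-value is a permutation approximation (above).
- The model assumes Gaussian log10 activity with homoscedastic
  components across dose groups; no heteroscedastic or autoregressive
  alternatives are implemented.
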