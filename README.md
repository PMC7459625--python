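# locomix

Mixed-effects analysis of rodent locomotor activity after acute
irradiation.

## The problem

Whole-body exposure to ionizing radiation suppresses spontaneous
locomotor activity in rodents within hours, followed by recovery over
days — a behavioural correlate of the prodromal radiation syndrome.
Quantifying *how much* activity drops at a given dose, and *how fast* it
recovers, requires more than per-day group comparisons: activity data
are longitudinal, with large stable differences between animals and
shared night-to-night fluctuations (room temperature, humidity, noise)
that both inflate naive standard errors and bias trend estimates.

`locomix` implements the full analysis pipeline for such experiments:
infrared-sensor movement counts are reduced to one nocturnal activity
value per animal per day, log-transformed, and modelled with a
**non-linear mixed effects model (NLMM) with crossed random effects**
for animal and day. The package is aimed at researchers analysing
repeated-measures activity data from small-animal irradiation (or
similar intervention) experiments.

## The model

Let `y_it` be the log10 nightly activity of animal `i` (dose `D_i`, Gy)
on day `t` (day 0 = irradiation):

```
y_it = f(t | D_i, θ) + δ_i + η_t + ε_it

f(t | D, θ) = ξ0 + ξ1 t + ξ2 t²
              − (β1 D + β2 D²) · exp[−ω1 e^{−ω2 (D − D0)} · t] · h(t)

δ_i ~ N(0, ψ²),   η_t ~ N(0, φ²),   ε_it ~ N(0, σ²)   (independent)
```

- `ξ0 + ξ1 t + ξ2 t²` — baseline drift common to all animals;
- `β1 D + β2 D²` — magnitude of the activity drop at irradiation
  (linear if `β2 = 0`, quadratic otherwise);
- `ω1 e^{−ω2(D−D0)}` — exponential recovery rate, `ω1` at the centering
  dose `D0` (default 2.75 Gy), dose-modulated when `ω2 ≠ 0`;
- `h(t)` — Heaviside step switching the drop/recovery term on at day 0.

The crossed random effects make the stacked observations jointly
Gaussian with covariance
`Cov(y_it, y_jt') = ψ²·1{i=j} + φ²·1{t=t'} + σ²·1{both}`.
Estimation is direct maximum likelihood (L-BFGS-B on the exact Gaussian
log-likelihood); submodels — any toggling of `{ξ1, ξ2, β2, ω2}`, mixed
or ordinary regression (`ψ² = φ² = 0`) — are compared by AIC. Animal
and day effects are predicted by posterior means (BLUPs), and the fitted
dose–response (drop at day 0 with delta-method 95% CIs, recovery rate,
recovery time) is exported per dose group.

## Worked example

Simulate an experiment at the package's reference operating point
(16 rats, 4 dose groups × 4 rats at 0/2.0/3.5/5.0 Gy, days −3..20) and
fit the optimal model structure:

```python
import locomix as lm

truth = lm.simulate_panel(lm.SimulationDesign(seed=11))
result = lm.fit(truth.panel, lm.OPTIMAL_NLMM)
print(result.table().round(4).to_string(index=False))
```

```
parameter  estimate       se   ci_lower  ci_upper  p_value     kind
      xi0    4.3099   0.0133     4.2839    4.3359   0.0000    fixed
    beta1    0.0477   0.0175     0.0133    0.0820   0.0032    fixed
    beta2   -0.0030   0.0035    -0.0098    0.0038   0.1914    fixed
   omega1   15.1639 747.2693 -1449.4569 1479.7848   0.4919    fixed
     psi2    0.0017   0.0006     0.0005    0.0029   0.0033 variance
     phi2    0.0016   0.0005     0.0006    0.0026   0.0006 variance
   sigma2    0.0015   0.0001     0.0013    0.0017   0.0000 variance
```

`xi0 ≈ 4.31` says untreated animals make about `10^4.31 ≈ 20,000`
movements per night; `beta1 ≈ 0.048` is the per-Gy drop in log10
activity at day 0. The huge `omega1` standard error is expected: at a
recovery rate of ~9/day the drop has vanished by day 1, so the data
carry almost no information about how *much* faster than "within a day"
the recovery was (p-values are one-sided, see the methods note).

```python
print(f"loglik={result.loglik:.2f}  AIC={result.aic:.2f}  BIC={result.bic:.2f}")
shares, display = lm.variance_shares(result.delta)
print("variance shares (%):", display)
est = lm.initial_decrease(5.0, result)
print(f"decrease at 5 Gy: {est.decrease:.3f} "
      f"(95% CI {est.ci_lower:.3f}-{est.ci_upper:.3f})")
pred = lm.predict_random_effects(result, truth.panel)
dw, p = lm.durbin_watson(pred.eta_hat, seed=0)
print(f"Durbin-Watson of day effects: {dw:.2f} (permutation p = {p:.3f})")
```

```
loglik=642.05  AIC=-1270.10  BIC=-1242.45
variance shares (%): (35, 34, 32)
decrease at 5 Gy: 0.163 (95% CI 0.112-0.213)
Durbin-Watson of day effects: 1.96 (permutation p = 0.927)
```

The three variance components split roughly evenly between animal,
day and measurement error; the 5 Gy group dropped by 0.163 log10 units
(a factor of ~0.69 in movements) at irradiation; and the predicted day
effects show no serial correlation (DW ≈ 2).

The same pipeline runs from the shell:

```bash
locomix simulate --out-panel panel.csv --seed 11
locomix fit --panel panel.csv --model optimal-nlmm \
        --out-json fit.json --out-table fit.csv
locomix select --panel panel.csv --out-table candidates.csv
locomix diagnose --panel panel.csv --fit-json fit.json --out-dir diag/
```

and `locomix preprocess` turns raw per-minute count CSVs into the panel
(nightly 18:00–06:00 sums, log10, day index relative to the irradiation
date).

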