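# turnoverkit

Protein-turnover kinetics for bacterial growth-phase transitions: why does a
short-lived, protease-degraded protein — the replication initiator DnaA under
Lon control is the motivating case — vanish when a culture enters stationary
phase? Is degradation speeding up, or is synthesis shutting down?

`turnoverkit` answers this with a small, fully testable analysis chain over
tidy CSV tables:

- **Forward model.** First-order turnover with a time-varying degradation
  rate,

  dP/dt = k_s − k_d(t)·P(t),  k_d(t) = a·t + k_d(0),

  where k_s is a constant synthesis rate, k_d(t) accelerates linearly, and
  dilution by growth is neglected (the half-life is always much shorter than
  the doubling time). Numerical (adaptive RK), closed-form, and
  quasi-steady-state (P ≈ k_s/k_d(t)) solutions are provided and
  cross-checked to ≤1e-6.
- **Chase assays.** Half-lives from synthesis shut-off time courses by pooled
  log-linear regression (t½ = −1/slope on log₂ intensities), with censored
  reporting ("> 120 min") when no significant decay is detected over the
  chase.
- **Degradation fit.** Best-fit (k_s, a) to an abundance time course by
  relative least squares, Σ((P_model − P_obs)/P_obs)², with k_d(0) anchored
  by the measured exponential-phase half-life and a multi-start bounded
  optimizer.
- **Synthesis inference.** Point-wise k_s(tᵢ) = dP/dt + k_d(tᵢ)·P(tᵢ) using
  a global linear slope for dP/dt and chase-derived half-lives per time
  point; dividing by the normalized mRNA profile gives a per-transcript
  translation rate.
- **qPCR.** Relative mRNA abundance by the comparative Ct method
  (fold = 2^(−ΔΔCt), endogenous reference, explicit calibrator).
- **Synthetic data.** Seeded generators for logistic growth curves,
  densitometry-like abundance courses (lognormal noise, replicates), chase
  decays and Ct tables, so every stage is validated by parameter recovery
  against known ground truth.

## Worked example

The `analysis/` scripts run the whole study on synthetic data. Generate the
inputs, then ask what the measured degradation kinetics alone could explain:

```sh
$ python analysis/01_simulate_inputs.py --seed 1
$ python analysis/03_degradation_scenarios.py
constant_23min: abundance decrease by 400 min (OD 1.5) = 0.0%
measured_23_to_20min: abundance decrease by 400 min (OD 1.5) = 26.0%
bestfit_23_to_9.1min: abundance decrease by 400 min (OD 1.5) = 79.0%
```

A half-life shortening from 23 min (exponential phase, OD600 0.4) to 20 min
(stationary onset, OD 1.0, reached 160 min later) removes only ~26% of the
protein by the stationary plateau (OD 1.5, 400 min) — nowhere near the
observed collapse. The half-life would have to fall to ~9 min to do the job,
which the chase assays rule out:

```sh
$ python analysis/02_chase_halflives.py
exponential: 24.3 min (95% CI 20.4-30.1)
lon_minus: > 120 min (censored)
stationary_onset: 19.2 min (95% CI 16.4-23.2)
exponential - stationary difference: 5.13 min (95% CI -0.03 to 10.29) ...
```

So the decline must come from synthesis. The point-wise estimator makes that
quantitative:

```sh
$ python analysis/05_synthesis_translation.py
global abundance slope: -0.00232/min
synthesis fold change over the growth curve: 18.9x down
terminal mRNA fraction: 0.80
terminal translation fraction: 0.066 (per-transcript synthesis at stationary onset vs exponential phase)
[generating truth: synthesis fold 20, terminal translation 0.077]
```

Synthesis falls ~19-fold while mRNA stays high, so the per-transcript
translation rate drops to a few percent of its exponential-phase value — the
regulation is translational. The bracketed line compares the inference
against the scenario's generating truth (a 20-fold synthesis decline with an
mRNA floor of 0.65).

The same stages are available as a CLI (`turnoverkit generate | halflife |
fit | infer-synthesis | qpcr | run`) for use on real quantifications.

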