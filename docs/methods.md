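# Methods

## The turnover model

Protein abundance follows first-order turnover with time-varying degradation,

    dP/dt = k_s − k_d(t) · P(t),        k_d(t) = a·t + k_d(0),

with P dimensionless (normalized to the exponential-phase value), time in
minutes from the exponential-phase reference point (OD600 0.4), k_s in
relative units per minute and a in min⁻². Growth dilution is omitted: the
modelled protein's half-life (9–25 min) is always far below the culture
doubling time, so proteolysis dominates removal. The culture time axis is
tied to optical density through a monotone piecewise-linear map anchored at
(0 min, OD 0.4), (160 min, OD 1.0) and (400 min, OD 1.5).

Schedules are parameterized by half-life anchors: k_d(0) = ln2/t½(0) and a
chosen so that t½(t₁) hits a second measured half-life. A schedule variant
can *clamp* after t₁, holding k_d at its t₁ value — the regime the chase
assays support, where degradation stops accelerating once stationary phase
begins. Construction rejects any schedule whose rate is not strictly
positive across its window; negative a (decelerating degradation) is allowed
so the fitter can explore both signs.

Three solutions are implemented and cross-checked:

- **Numerical**: adaptive Runge–Kutta (rtol 1e-8, atol 1e-12). The contract
  is agreement with the closed form to ≤1e-6 relative, not a particular
  integrator.
- **Closed form**: P(t) = P(t₀)e^(−ΔC) + k_s ∫ e^(C(s)−C(t)) ds with
  C(t) = ∫k_d. The integrand is bounded by 1 whenever k_d > 0, so the
  integral is evaluated stably by composite Gauss–Legendre (16 nodes per
  panel, ≤2 units of exponent change per panel, tails beyond e⁻⁶⁰
  truncated), giving ~1e-14 accuracy per segment. Chaining segments between
  requested times makes this the fast forward map used inside the fitter
  and the piecewise-synthesis generator.
- **Quasi-steady state**: P ≈ k_s/k_d(t), valid when the half-life is short
  against the timescale of k_d change; the full solution lags above it by
  O(a·k_s/k_d³).

## Half-life estimation from chase assays

After translation shut-off, intensities are normalized per replicate to the
t = 0 band and pooled; log₂(intensity) is regressed on time by ordinary
least squares and t½ = −1/slope. Pooling (rather than averaging replicates
first) keeps replicate scatter in the slope standard error, from which a
two-sided 95% CI is propagated (−1/slope at the slope CI endpoints; delta
method for comparisons between estimates). Non-positive intensities are
dropped, not floored — flooring would bias the slope.

An estimate is **censored** when the one-sided test for a negative slope is
not significant at α = 0.05 or the fitted half-life exceeds the chase
duration; it is then reported as "> duration" (e.g. "> 120 min" for a
stable protein over a 120-min chase) and never extrapolated.

## Degradation fit

Given an abundance series and the exponential-phase half-life, the fitter
minimizes the sum of squared *relative* residuals Σ((P_model−P_obs)/P_obs)²
over (k_s, a), with k_d(0) fixed by the measured anchor and P(0) pinned to
the first observation. Relative residuals weight the small late values the
same as the early ones, which matters because the biology lives in the
decline; a log-residual objective is available as an option. Bounds:
k_s ∈ [0, 10·k_d(0)·P(0)], a ∈ [−0.99·k_d(0)/t_end, 1] (the lower bound
keeps k_d positive on the window). Nine deterministic grid starts plus four
seeded jittered starts feed L-BFGS-B; the best converged minimum wins, and
identical data and seed give identical results. The label-masked "overnight"
point is excluded by default. Scenario prediction evaluates alternative
schedules under steady-state synthesis on the data's grid.

## Point-wise synthesis and translation inference

Rearranging the balance gives k_s(tᵢ) = dP/dt + k_d(tᵢ)·P(tᵢ). dP/dt is a
single global OLS slope through the (non-overnight) abundance points —
appropriate when the decline is near-linear, which the data and the default
scenario both are; a per-point finite difference would amplify densitometry
noise. Half-lives are assigned per point (first half of the series → the
exponential-phase value, second half → the stationary-onset value, for the
canonical 4-point series "first two / last two"; an explicit map file
overrides this). Negative inferred rates are retained with a warning rather
than clipped — they flag inconsistent inputs. Profiles are normalized to
their first point (the figure-axis convention assumed here; a maximum-based
normalization would only rescale).

Translation rates divide the normalized synthesis profile by relative mRNA
abundance matched by OD600 (nearest qPCR sample within 0.1 OD, since both
assays sample on OD grids), renormalized to the first protein point.

## Comparative Ct

Replicate Cts are averaged on the Ct scale; ΔCt = Ct_target − Ct_reference,
ΔΔCt against an explicit calibrator sample, fold = efficiency^(−ΔΔCt) with
efficiency fixed at 2.0 (perfect doubling; a per-gene efficiency can be
passed). Replicate SD is propagated to the fold scale by the delta method
(sd_fold = fold·ln(eff)·sd_ΔΔCt). Wells failing the dissociation-curve QC
flag are excluded with a logged count. Invariants: a global Ct shift leaves
folds unchanged; target = reference returns 1 everywhere; swapping sample
and calibrator inverts the fold.

## Synthetic data

The generators emulate the study's measurements under known truth:

- **Growth**: logistic OD(t) = K/(1 + ((K−od0)/od0)e^(−rt)) with defaults
  od0 = 0.4, K = 1.5 and r = ln(5.5)/160 ≈ 0.01065 min⁻¹ solved so the
  culture passes OD 1.0 at 160 min — matching the time–OD anchors above.
- **Densitometry**: abundance from the forward solver times unit-mean
  multiplicative lognormal noise, default CV 10%, with replicates (default
  3) reported as mean ± SD, as blot quantifications are.
- **Chases**: 2^(−t/t½) per replicate with the same noise model; sampling
  every 10 min.
- **qPCR**: Ct_target = base − log₂(rel_expr) + jitter over a constant
  reference gene, Gaussian jitter of 0.2 cycles, triplicates.

Time-varying synthesis is piecewise-constant; a profile's value *at* a
change time is the rate in force on the segment ending there, so the
point-wise estimator inverts the generator exactly at sample times. Change
points may be finer than the sampling grid: the default scenario builds a
20-fold synthesis collapse on a 10-min grid whose continuous envelope,
k_s(t) = s + k_d(t)(1 + s·t), makes abundance fall exactly linearly
(1 → 0.105 over 400 min) — the near-linear decline regime in which the
global-slope estimator is consistent. The scenario's degradation truth uses
the clamped 23 → 20 min schedule; the mRNA truth declines linearly to a
floor of 0.65, so the true terminal translation fraction is
0.05/0.65 ≈ 0.077.

All randomness flows through explicit integer seeds (child seeds derived
via `SeedSequence`); identical scenario + seed reproduce every table
byte-for-byte.

What the generators do **not** emulate: gel-loading and transfer artifacts,
blot saturation, correlated within-replicate errors, primer-efficiency
drift, growth-curve irregularities. Passing recovery tests therefore shows
the estimators are consistent and correctly implemented under the stated
noise model, not that they are robust to every real-data pathology.

## Problem sizes and numerical choices

The default scenario samples 9 abundance points (0–400 min, every 50 min;
3 replicates), 5-point chases for the wild-type-like conditions and a
13-point 120-min chase for the stable control, and a 9-sample qPCR panel in
triplicate. Monte-Carlo calibration uses 500 four-point chases for the
half-life estimator and 20 fit replicates (on 3-replicate mean series) for
the degradation fitter. Ties and degenerate inputs: perfectly flat chases
censor rather than fit; fewer than 3 usable points is an input error;
abundance series must be strictly increasing in time with positive values.

## Known limitations

- The global-slope dP/dt estimator is biased when the protein decline is
  strongly curved; the package reports it regardless, as the procedure is
  defined that way, and the forward-model consistency test quantifies the
  deviation (<2% near steady state, a few percent under the default
  scenario).
- The relative-least-squares fit treats observation errors as independent
  and homoscedastic on the relative scale; replicate SDs are not used as
  weights.
- Censored half-lives carry no likelihood information beyond the bound; no
  survival-style inference is attempted.
- The comparative Ct method assumes equal amplification efficiency between
  target and reference unless an efficiency is supplied.
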