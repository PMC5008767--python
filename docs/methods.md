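# Methods

## Model

A 1-D activity series x(t), sampled at interval Δt, is modelled as a
discrete Langevin (Euler–Maruyama) process in unit time steps:

    δx(t) = x(t+1) − x(t) = g(x(t)) + ξ(t).

Working in unit steps loses no generality for the noise analysis: rescaling
ξ by any constant leaves the tail law |ξ|^(−1−α) — and hence α — unchanged,
so the characteristic exponent is independent of the sampling interval. The
physical Δt (default 2 s) is carried as metadata and only re-expresses τ in
seconds.

Assumptions:

* **Additive, i.i.d. noise.** ξ(t) is independent of x(t) and of its own
  past, with a single stable law per network. State-dependent
  (multiplicative) noise is out of scope.
* **Linear relaxation drift.** g(x) = −k(x − x*) with k ∈ (0, 1) per unit
  step. The noise-free path is then the exponential relaxation
  ⟨x(t)⟩ = x* + (x0 − x*)e^(−t/τ) with τ = 1/k (discretely, (1−k)^t).
  k ≥ 2 makes the unit-step map oscillatory/divergent and triggers a
  warning.
* **Zero-location noise.** "⟨ξ⟩ = 0" is encoded as zero location in Nolan's
  S0 form, because the mean does not exist for α ≤ 1; for symmetric noise
  this is median-centering. This keeps the drift identifiable over the whole
  α range.

## Stable-law numerics (`stable`)

Parameters are reported in the classical S1 form (the parameterization in
which the characteristic function reads
exp(iδt − γ^α|t|^α[1 − iβ sign(t) tan(πα/2)]) for α ≠ 1, with the
2/π·ln|t| skew term at α = 1). All internal numerics use Nolan's S0 form,
which is continuous in α across 1; a guard band |α − 1| < 10⁻³ snaps to the
dedicated α = 1 branch. The S0↔S1 conversion is an involution and is tested
as such.

* **Sampling** is the Chambers–Mallows–Stuck transform, with the separate
  α = 1 branch, driven by a single injectable `numpy` Generator.
* **Density / distribution** come from Fourier inversion of the CF. The
  integrand A(t)·trig(wt − g(t)) is split against its dominant linear phase
  w and integrated with oscillatory-weighted (QAWO) quadrature, which stays
  accurate at any frequency — plain adaptive quadrature fails for small α
  where |φ(t)| = e^(−t^α) decays slowly. The Gil-Pelaez formula gives the
  CDF; its 1/t singularity is handled by a short leading segment covering a
  bounded number of cycles.
* **Tail branch.** Far from the mode the first-order Pareto asymptote
  F̄(x) ≈ C_α(1+β)γ^α x^(−α), C_α = sin(πα/2)Γ(α)/π, replaces quadrature.
  Because the asymptote's relative error is O(x^(−α)), the switch requires
  *both* |x−δ| > 25γ *and* x^(−α) below 5·10⁻⁴ (10⁻² for the density, whose
  absolute quadrature floor dominates sooner). With the fixed 25γ switch
  alone, normalization errors reach 6·10⁻³ at α = 0.6.
* **Closed forms** (normal at α = 2, Cauchy at α = 1, β = 0, Lévy at
  α = 0.5, β = ±1) short-circuit the quadrature and anchor the tests.

Against independent reference values (scipy's `levy_stable`, used nowhere in
the implementation), pdf and cdf agree to ~10⁻¹⁰ over the tested grid.

## Synthetic cohorts (`cohort`)

`generate_cohort` emulates a multi-subject resting-state experiment: default
25 subjects × 850 time points at Δt = 2 s, one (k, x*, α, β, γ) truth per
network, subseeds derived deterministically from (seed, subject, network).
The first 100 steps are discarded (burn-in) so series start near
stationarity; x0 defaults to x* plus one noise draw. An optional linear
trend exercises the detrending stage (off by default — the cohorts are
trend-free unless asked).

What the generator deliberately does **not** emulate: hemodynamic response
convolution, scanner drift and physiological artifacts, spatial mixing
between networks, or preprocessing filters. A green end-to-end test
establishes that the estimation chain recovers the parameters of the stated
Langevin world, not that real recordings satisfy that model.

## Drift recovery (`drift`)

The drift is the conditional location of δx given x, estimated by binning:

* **equal-occupancy bins** (default 50, minimum 20 points each) rather than
  equal width — heavy-tailed marginals starve equal-width bins;
* bins outside the 1st–99th percentile of x are dropped (rare excursions
  otherwise dominate the fit through leverage);
* per-bin location statistic: **mean** (default, the conditional
  expectation) or **median** (robust option). The bin *center* uses the same
  statistic as the aggregate — pairing a mean center with a median aggregate
  biases the slope in skewed bins;
* weighted least squares through (center, aggregate) with occupancy weights;
  k = −slope, x* = intercept/k, with slope standard error and R².

A non-negative fitted slope flags the model as non-relaxing (k set to 0, x*
reported as the occupancy-weighted mean activity) rather than raising.

The conditional mean is unbiased for any α > 1 but its bin averages have
heavy-tailed noise; the conditional median is dramatically more stable under
Lévy noise (k̂ = 0.304 ± 0.004 vs 0.27 ± 0.15 at α = 1, pooled 10 × 850
points) and is what the pipeline uses by default (see below).

## Noise characterization (`noise`)

Residuals ξ(t) = δx(t) + k(x(t) − x*) feed two estimators on their natural
inputs:

* **ECF regression (primary).** Signed residuals. McCulloch's quantile
  tables give starting values for (α, β); the scale/location seeds are IQR/2
  and the median — the Koutrouvelis regressions re-estimate γ and δ at every
  iteration, so the initializer only needs the right order of magnitude.
  The iteration alternates (i) the modulus regression
  log(−log|φ̂(t)|²) = log(2γ^α) + α·log t on t_k = πk/25 and (ii) the
  argument regression arg φ̂(u) = δu + βγ^α tan(πα/2)·sign(u)|u|^α on
  u_l = πl/50, with the standard (α, n)-dependent point counts, until α and
  γ stabilize. α̂ is clamped to (0, 2] (snapping to exactly 2 zeroes β,
  which is unidentifiable there), β̂ to [−1, 1]. Known limitation: for
  α ≈ 1 with β ≠ 0 the iterative rescaling ignores the S1 location shift
  (2/π)βγ·ln γ, leaving a small bias in δ̂ only.
* **Survival tail slope (diagnostic).** Magnitudes |ξ|. The empirical
  survival function assigns i/n to the i-th largest magnitude (ties share
  the higher value, so log F̄ is always defined); OLS on the top
  `tail_fraction` of points in log–log coordinates gives α̂_tail = −slope,
  with a Hill estimator on the same exceedances as a cross-check. Default
  fraction 0.1 with a sensitivity sweep over {0.05, 0.1, 0.2} recorded in
  every report, because the asymptotic regime starts further out as α → 2:
  at n = 10⁵ the top decile carries a systematic +0.2 bias at α = 1.6,
  while the 0.05 window is already asymptotic (bias +0.11). Estimates with
  α̂_tail > 2 or log–log R² < 0.95 are flagged as non-power-law (the
  Gaussian case).

Measured calibration of the ECF route: mean |α̂ − α| ≤ 0.015 at n = 10⁴
over α ∈ {1.0, 1.2, 1.5, 1.8, 2.0} (20 seeds each).

## Goodness of fit (`gof`)

The fitted law has no closed-form CDF, so fits are validated by a *matched
two-sample* comparison: draw exactly as many samples from the fitted law as
there are residuals and run the two-sample Kolmogorov–Smirnov test
(asymptotic p-values) and the Scholz–Stephens two-sample Anderson–Darling
test, which weights tail discrepancies — the regime where stable laws
differ. scipy's asymptotic A-D p-value is interpolated from critical values
and clipped to [0.001, 0.25]; decisions at the 0.05 level are unaffected,
and an exact-permutation option (recommended below ~100 points) returns
uncapped p-values. `mc_power` estimates rejection rates over replicated
sample pairs; with alt = null it is the empirical type-I error, which sits
at 0.05 ± 0.01 for both tests at n = 500. Across networks, per-network
decisions are reported raw (the headline) with Holm-adjusted p-values as a
supplementary column.

## Pipeline (`pipeline`, `cli`)

Per network: detrend each subject (default: subtract the OLS line in t) →
pool (x, δx) across subjects → drift fit → per-subject residuals → pooled
stable fit + tail sweep → matched GoF → percentile-bootstrap CIs (B = 200)
→ α ranking across networks.

Two robustness choices depart from the naive chain, both driven by measured
failure modes under heavy tails (α ≈ 1, 850 points/subject):

* **Median drift aggregation by default.** Single extreme increments can
  destroy a mean-aggregated bin and with it the pooled slope; the median
  variant is the package's own robust option promoted to the pipeline
  default (the low-level `estimate_drift_curve` keeps the conditional mean
  as its default).
* **Per-subject residual centering.** Detrending leaves every subject with
  its own random location error — with Lévy noise these offsets are large,
  and pooling then mixes shifted laws, biasing α̂ by up to ~0.4. Each
  subject's residuals are median-centered before pooling
  (`center_residuals=True`). With this, α̂ errors stay within ±0.1 at
  α = 1.0–1.1 under linear detrending; without detrending, recovery is
  near-exact (k within ±0.012, α within ±0.025).

Known limitation: under linear detrending with α ≲ 1.2 noise, k̂ remains
attenuated (per-subject OLS lines make the effective equilibrium
time-varying, which no autonomous drift model can absorb). α̂ and the α
ranking are insensitive to this; k̂ from heavy-tailed detrended data should
be read with its R² and the heavy-tail warning the pipeline logs whenever
α̂ ≤ 1.2.

Failures are isolated per network (a failed report with a reason, never a
crashed run); reports are byte-identical under a fixed seed and config.

## Defaults at a glance

| parameter | default | why |
|---|---|---|
| Δt | 2 s (metadata) | typical fMRI repetition time; analysis is Δt-invariant |
| n_subjects × n_timepoints | 25 × 850 | emulated cohort shape |
| burn-in | 100 steps | start near stationarity |
| drift bins / min count | 50 / 20 | ≈ n/50 points per bin, stable conditional estimates |
| x-trim | 1st–99th pct | leverage control under heavy tails |
| ECF floor | 200 residuals | below this the CF regressions are unstable |
| tail_fraction | 0.1 (+ sweep 0.05/0.2) | bias–variance compromise; sweep shows sensitivity |
| GoF level | 0.05 | conventional; matched two-sample design |
| bootstrap B | 200 | percentile CIs at acceptable cost |
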