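# levylangevin

Langevin drift–diffusion modelling of noisy 1-D activity time series with
**α-stable noise** — for researchers who want to know not just *how much* a
signal fluctuates, but *what kind* of stochastic process drives it.

Resting-state brain networks (and many other physiological and physical
systems) produce fluctuating signals whose character differs sharply: some
hover inside a narrow band of small, even fluctuations, others show long
quiet stretches punctuated by sudden large jumps. `levylangevin` separates
each series x(t) into a deterministic relaxation and a stochastic term by
fitting the discrete Langevin (Euler–Maruyama) model

    δx(t) = x(t+1) − x(t) = g(x(t)) + ξ(t),
    g(x) = −k (x − x*),

where the drift g pulls activity back to an equilibrium x\* with
characteristic time τ = 1/k, and the noise ξ is i.i.d. **α-stable**
f(x; α, β, γ, δ). The characteristic exponent α places each signal on a
spectrum of dynamics:

* **α = 2** — Gaussian noise, ordinary Brownian-style fluctuation;
* **α < 2** — Lévy noise with power-law tails p(|ξ|) ∼ |ξ|^(−1−α):
  occasional jumps far larger than anything a Gaussian process produces.

The package recovers g(x) nonparametrically (binned conditional increments),
fits the full four-parameter stable law to the residuals ξ = δx − g(x) by
regression on the empirical characteristic function (McCulloch
initialization + Koutrouvelis refinement), cross-checks α against the
log–log slope of the survival function F̄(|ξ|), and validates every fit with
two-sample Kolmogorov–Smirnov and Anderson–Darling tests plus Monte Carlo
power/type-I calibration. A synthetic-cohort generator with known ground
truth makes the entire chain testable end to end.

## Worked example

```python
import levylangevin as ll

# a stated world: three networks, 10 subjects, 850 samples at dt = 2 s
spec = ll.CohortSpec(
    networks=[
        ll.NetworkTruth("heavy", ll.DriftModel(k=0.3, x_star=1.0), ll.centered_noise(alpha=1.1)),
        ll.NetworkTruth("mid",   ll.DriftModel(k=0.3, x_star=0.0), ll.centered_noise(alpha=1.5)),
        ll.NetworkTruth("gauss", ll.DriftModel(k=0.3, x_star=-1.0), ll.centered_noise(alpha=2.0)),
    ],
    n_subjects=10, n_timepoints=850,
)
cohort = ll.generate_cohort(spec, seed=1)

reports = ll.run_pipeline(cohort, ll.PipelineConfig(bootstrap_reps=0, seed=1))
for r in reports:
    print(f"{r.network_id:6s} alpha={r.stable_params.alpha:.3f} "
          f"rank={r.alpha_rank} KS p={r.gof.ks_pvalue:.2f}")
```

Output:

```
gauss  alpha=2.000 rank=3 KS p=0.29
heavy  alpha=1.157 rank=1 KS p=0.35
mid    alpha=1.506 rank=2 KS p=0.57
```

The fitted characteristic exponents recover the injected values (1.1, 1.5,
2.0) within 0.06, the α ranking identifies which network is most Lévy-like,
and the two-sample K-S p-values show the fitted stable laws are consistent
with the extracted residuals at the 0.05 level.

The estimators also compose individually, sklearn-style:

```python
ts    = cohort[0]                                   # one subject x network trace
drift = ll.LinearDriftEstimator().fit(ts)           # drift.k_, drift.x_star_, drift.tau_
xi    = ll.extract_residuals(ts, drift.model_)      # xi(t) = dx(t) - g(x(t))
fit   = ll.StableECFEstimator().fit(xi)             # fit.alpha_, fit.beta_, fit.gamma_, fit.delta_
tail  = ll.TailSlopeEstimator().fit(xi)             # tail.alpha_tail_, tail.hill_alpha_
check = ll.gof_assess(xi, fit.params_, seed=0)      # K-S + A-D against the fitted law
```

## Command line

```bash
levylangevin simulate --config cohort.yaml --seed 1 --out sim/
levylangevin fit      --input sim/cohort.csv --seed 1 --out reports/
levylangevin gof      --residuals xi.csv --alpha 1.5 --seed 1 --out gof.json
levylangevin power    --config power.yaml --seed 1 --out power.csv
```

`fit` writes one JSON per network, a `summary.csv`
(network, k, x\*, α, β, γ, δ, tail-α, K-S p, A-D p, rank), plot-ready CSVs
for the drift and survival curves, and a run manifest with every seed used.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from freshly generated data, the package's headline calibration
quantities: the empirical type-I error of the two-sample K-S test at the
0.05 level (1000 same-law pairs of n = 500 stable samples), and the
characteristic exponent / skewness the ECF estimator recovers from the three
closed-form members of the stable family — normal draws (α = 2), the
tan-transform of uniforms (Cauchy, α = 1) and 1/Z² for standard normal Z
(Lévy, α = 0.5, β = 1). Each generator is independent of the package's own
sampler.

See `docs/methods.md` for the model assumptions, estimator details,
numerical choices and known limitations.
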