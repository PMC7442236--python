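# stagegrow

Multistage Bayesian von Bertalanffy growth modelling for organisms with
distinct life-history stages, built around the sampling realities of
pond-breeding amphibian monitoring: aquatic larvae are dip-netted
cross-sectionally with *known* ages (age 0 = pond filling), metamorphs are
measured once as they leave the wetland, and terrestrial adults are
PIT-tagged at drift fences and remeasured on later breeding migrations with
*unknown* ages. `stagegrow` reconciles all three data streams into one
hierarchical model and fits it by MCMC.

## The model

Lengths are snout-vent length (SVL, mm); time is in years.

**Larval stage** (known age *t*):

    L(t) = L∞ (1 − e^(−k_L (t − t₀)))

**Metamorphosis** at a latent age *t_m* ~ U(0.2, 0.7) per individual gives the
length at metamorphosis L_tm = L(t_m) on the larval curve.

**Adult stage**, for an individual first captured at latent age *t* and
remeasured δt years later:

    L(t + δt) = L∞ᵢ − (L∞ᵢ − L_tm)·e^(−k_A (t + δt − (t_m + t₀)))

Latent ages at first capture follow a lognormal with median α, truncated to
(t_m, 20) years; individual asymptotes L∞ᵢ ~ N(μ_L∞, σ²_L∞) truncated below
at the individual's length at metamorphosis. Observed lengths are Gaussian
around the curve with variance σ²_L shared across stages. Priors are vague:
uniforms on μ_L∞ ∈ (30, 100), t₀ ∈ (−2, 2), α ∈ (0.5, 20) and Gamma(0.1, 0.1)
(shape–rate) on the rates and variances.

Fitting is by an adaptive componentwise Metropolis-within-Gibbs sampler
(log/logit-transformed random-walk proposals, adaptation during burn-in
only), with a joint scaling move along the k_A/latent-age posterior ridge.
Diagnostics include classic Gelman–Rubin PSRF, the Brooks–Gelman
multivariate PSRF, autocorrelation-based effective sample sizes, and
posterior-predictive (Bayesian) p-values for larval sizes and adult growth
increments. A synthetic-data generator with the exact generative structure
of the model stands in for field data.

## Worked example

```bash
stagegrow simulate --seed 1 --out data/            # three CSVs + truth.json
stagegrow fit --data data/ --preset reduced --seed 1 --out fit/
stagegrow diagnose --draws fit/draws.csv --data data/ --out fit/diagnostics.json
stagegrow report --draws fit/draws.csv --out fit/
```

The reduced preset (3 chains × 20,000 iterations, burn-in 5,000, thin 10)
fits the default synthetic dataset (411 larvae, 766 metamorphs, 927 adults)
in a few minutes. `report` prints, for example:

```
time to 35 mm: 26.6 weeks (95% CrI 26.4-26.9)
wrote fit/summary.csv and fit/report.json
```

i.e. the posterior time for a larva to reach the ~35 mm size needed for
metamorphosis, with its 95% credible interval. `summary.csv` holds posterior
means and 95% CrIs for the eight population parameters; `report.json` adds
first-year adult growth, the predicted adult age distribution (with its
97.5th percentile as a longevity proxy) and the growth curve with credible
and posterior-predictive bands. The full protocol (3 × 500,000, burn-in
100,000, thin 100) is the default when no preset is given.

Equivalent library calls:

```python
import stagegrow as sg

ds, truth = sg.simulate_dataset(sg.SimulationConfig(seed=1))
samples = sg.run_mcmc(ds, sg.default_priors(),
                      sg.FitConfig(n_iter=20_000, n_burnin=5_000, thin=10, seed=1))
print(sg.summarize(samples, samples.population_names()))
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the whole pipeline from scratch — simulate at the default generating
parameters, fit with the reduced preset, diagnose, and compute the derived
quantities — printing the posterior summary, convergence diagnostics and
derived quantities along the way, and writes the results manifest to the
given path.
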