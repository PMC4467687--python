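# decayfit

Biexponential fluorescence-lifetime estimation from binned single-photon
(TCSPC) count data, built for the very-small-sample regime — tens of
photons per histogram — where directly fitting an exponential mixture is
numerically fragile and prone to overfitting.

## The problem and the method

In single-molecule lifetime experiments a pulsed laser excites a
fluorophore and a time-correlated single photon counting (TCSPC) device
records each photon's delay time. Delay times X are modeled as a
two-component exponential mixture ("biexponential"),

    f(x) = (c/τ₁) e^(−x/τ₁) + ((1−c)/τ₂) e^(−x/τ₂),

and the data arrive binned: conditional on n detected photons, the counts
Y₁..Y_m in m bins of width δ are multinomial with window-normalized
probabilities p_j = [F(δj) − F(δ(j−1))] / F(δm). Often τ₁ is known from
controlled calibration and the goal is the minor component (c, τ₂).

With only ~50 photons the direct maximum-likelihood fit of (c, τ₂) — even
with 25 starting values — frequently collapses onto a parameter-space
boundary, runs off to physically absurd lifetimes, or overfits the sample
(small Pearson χ² against the data, large Hellinger distance to the true
curve). `decayfit` implements the **gamma-conversion estimator** as the
robust alternative:

1. fit a gamma decay model
   g(x) = x^(α−1) e^(−αx/τ_γ) / ((τ_γ/α)^α Γ(α)), shape α ∈ (0, 1],
   mean lifetime τ_γ, to the binned counts by multinomial maximum
   likelihood (Nelder–Mead, single start);
2. convert (α̂, τ̂_γ) to biexponential parameters by **moment matching** —
   equate the first two raw moments (τ₁ known), giving the closed form

       τ̂₂ = (2ατ_γτ₁ − (1+α)τ_γ²) / (2ατ₁ − 2ατ_γ),
       ĉ  = (1−α)τ_γ² / (2ατ₁² − 4ατ_γτ₁ + (1+α)τ_γ²),

   or the first three moments (τ₁ unknown), solved as the two-point
   Gauss-quadrature (Prony/Hankel) problem of the gamma's exponential
   mixing measure.

The package also ships the direct-fit baseline, the evaluation metrics
(Pearson χ², Monte-Carlo Hellinger distance, capped MSE, lifetime-ratio
quantiles), a seeded synthetic-data generator, and the full 30-configuration
simulation study comparing the two estimators. See `docs/methods.md` for
the model, the optimizer protocol, and known limitations (notably: the
gamma conversion is a small-sample approximation, not a consistent
estimator).

## Worked example

`python examples/fit_single_histogram.py` simulates one 50-photon dataset
from (c=0.75, τ₁=1500 ps, τ₂=750 ps) and fits it both ways:

```
dataset: 50 photons inside the 10000 ps window

[gamma conversion]
  alpha_hat     = 0.8253
  tau_gamma_hat = 1232.7 ps
  -> c_hat      = 0.6925
  -> tau2_hat   = 630.8 ps  (truth 750 ps)

[direct biexponential]
  c_hat       = 0.8029
  tau2_hat    = 240.6 ps  (truth 750 ps)

gamma: chi2 vs data = 159.0, Hellinger vs truth = 0.036
direct: chi2 vs data = 148.0, Hellinger vs truth = 0.090
```

The direct fit matches the observed counts slightly better (lower χ²) yet
lands farther from the true decay curve (larger Hellinger distance) with a
τ̂₂ off by a factor of three — overfitting in miniature. At study scale
(`python examples/run_small_study.py`, 20 replicates of each of the 30
grid configurations) the contrast is stark:

```
        n_datasets  n_failed  failure_proportion  capped_mse_ns2     q5   q50   q95
direct         600       310              0.5167            1649 0.1122 1.193  4922
gamma          600        42                0.07           43.58  0.235 1.009 4.351
```

The direct fit fails to deliver a physical biexponential on about half the
datasets and, where it does, its τ̂₂/τ₂ spread spans four orders of
magnitude; the gamma conversion fails on ~7% and stays within one.

Other entry points: `examples/gamma_conversion_math.py` (the
moment-matching identity by itself) and the `decayfit` CLI
(`decayfit fit`, `decayfit study examples/study_config.yaml --out out/`,
`decayfit subsample`, `decayfit version`).

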