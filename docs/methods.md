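# Methods

## Model

Photon delay times X ≥ 0 (picoseconds) follow a two-component exponential
mixture with weight c on lifetime τ₁ and 1−c on τ₂. Binned acquisition
over m bins of width δ conditions on the observation window [0, δm):
given n in-window photons, the counts are multinomial with

    p_j = [F(δj) − F(δ(j−1))] / F(δm),   j = 1..m,

for the model cdf F. Up to an additive constant, the negative
log-likelihood of any parametric cdf is

    n log F(δm) − Σ_j y_j log[F(δj) − F(δ(j−1))],

implemented once and shared by both estimators; the constant is taken as
zero. A bin with y_j > 0 and zero model probability makes the objective
+∞ rather than raising, so optimizers treat it as infeasible.

The gamma decay model has density
x^(α−1) e^(−αx/τ_γ) / ((τ_γ/α)^α Γ(α)) — shape α and **mean lifetime**
τ_γ (scale τ_γ/α). All interfaces use this (shape, mean) parameterization.
α is restricted to (0, 1]: there the density is completely monotone, i.e.
a continuous mixture of exponentials, which is the physically meaningful
regime for decay curves, and α = 1 is exactly the monoexponential with
lifetime τ_γ. The density diverges at x = 0 for α < 1; `gamma_pdf` returns
`inf` there (the likelihood only ever evaluates the cdf).

## Estimators

**Direct fit.** Maximize the binned likelihood over (c, τ₂) with τ₁ known
(or (c, τ₁, τ₂) free) by Nelder–Mead from 25 starts: c₀ = i/26,
i = 1..25, and every lifetime initialized to δ·(Σ_j j·y_j)/(Σ_j y_j) — the
mean occupied-bin index converted to time units. The best converged start
by objective value wins (ties: lowest start index); the fit fails only if
every start fails.

**Gamma conversion.** Fit (α, τ_γ) by the same likelihood from the single
start α₀ = 0.5, τ_γ,₀ as above, then map to biexponential parameters by
equating raw moments (derivatives of the moment generating functions at
zero). With τ₁ known, matching k = 1, 2 gives the closed form

    τ̂₂ = (2ατ_γτ₁ − (1+α)τ_γ²) / (2ατ₁ − 2ατ_γ)
    ĉ  = (1−α)τ_γ² / (2ατ₁² − 4ατ_γτ₁ + (1+α)τ_γ²),

returned exactly as (ĉ = 0, τ̂₂ = τ_γ) when α = 1. With τ₁ unknown,
matching k = 1, 2, 3 is solved numerically: dividing the k-th raw moment
by k! yields the power moments e_k = Σ w_i τ_i^k of the mixing measure
over lifetimes, so the lifetimes are the roots of the degree-2 Hankel
(Prony) recurrence and the weights follow from a Vandermonde solve — the
classical two-point Gauss-quadrature construction. For α < 1 the gamma is
completely monotone, so its mixing measure is a positive measure and the
construction always yields positive lifetimes and weights in [0, 1]. The
larger root agrees with the textbook closed form
τ_γ(√(2(2+α−α²)) + 2(α+1))/(6α), which the test suite uses as a
cross-check. A generic M-component solver (`moment_match_numeric`,
K = 2M−1 moments, optionally with fixed lifetimes handled by a
multi-start Newton root finder with relative-residual verification) serves
as the independent oracle for both closed forms and as the documented
extension path beyond two components.

Conversions falling outside the physical space (ĉ ∉ [0, 1], τ̂₂ ≤ 0, or no
real solution) are returned with `valid=False` and the raw values
preserved — never clipped; |τ_γ − τ₁| < 10⁻⁹·τ₁ triggers a degenerate
monoexponential branch (ĉ = 1, τ̂₂ undefined).

## Optimizer protocol

Both fits run Nelder–Mead **in the models' natural coordinates** with the
standard move coefficients (reflection 1, expansion 2, contraction 0.5,
shrink 0.5; initial simplex by 5% coordinate perturbation) and terminate
when the simplex function values satisfy

    f_worst − f_best ≤ reltol · (|f_best| + reltol),   reltol = 10⁻⁸,

with a 10,000-iteration cap. Domain constraints (0 ≤ c ≤ 1, 0 < α ≤ 1,
positive lifetimes) are enforced by the objective returning +∞ outside the
domain; the simplex never accepts such points, so no penalty terms distort
the likelihood values. This relative-f termination is the convergence
control classically used for lifetime fitting; scipy's Nelder–Mead offers
only absolute xatol/fatol criteria, which behave very differently when
lifetimes span six orders of magnitude, so the loop lives in
`decayfit.neldermead` (generic Python) with a numba-compiled twin
specialized to the biexponential likelihood (`decayfit._fastpath`) for the
25-start direct fit — the hot path of the simulation study. The test suite
asserts step-for-step agreement between the two implementations and checks
the minimizer against scipy on smooth benchmarks. A coordinate transform
(log lifetimes, logistic weight) was evaluated and rejected: it
qualitatively changes which local optima the multistart reaches (making
sub-bin-width "spike" optima and τ̂₂ ~ e⁷⁰⁰ runaways reachable) and makes
boundary-degenerate solutions impossible to observe as such.

## Failure accounting

At 50 photons the likelihood surface routinely has no interior optimum,
and "the fit failed" needs a definition. A method **fails to deliver** on
a dataset when its optimizer does not converge within the iteration cap
(or returns a non-finite objective), **or** the converged solution is not
a physical biexponential:

* gamma path — the moment conversion is invalid (τ̂₂ ≤ 0, ĉ ∉ [0, 1], or
  the degenerate τ_γ = τ₁ branch);
* direct path — the mixture collapsed onto the c boundary, defined
  scale-consistently as a component whose expected photon count
  min(ĉ, 1−ĉ)·n falls below 0.5: at ĉ → 0 the fit has abandoned the known
  τ₁ component entirely (a monoexponential, not a biexponential), and at
  ĉ → 1 τ̂₂ is unidentified.

Records carry both the raw optimizer flag (`converged`) and this
`delivered` flag; all study aggregates (failure counts, quantiles, MSE)
use `delivered`, and ratio quantiles and capped MSE are computed over the
datasets where **both** methods delivered, so the two methods are compared
on identical data.

## Evaluation metrics

* **Pearson χ²** against the fitted model's own expectations
  E[Y_j] = n·p_j, summed over all m bins; a bin with zero expectation
  contributes 0 when empty and +∞ when occupied (limit convention).
* **Hellinger distance** between the fitted and true biexponential
  densities, estimated by Monte Carlo: with z₁..z_N i.i.d. from the true
  density h, H ≈ √(2 − (2/N) Σ √(f(zᵢ)/h(zᵢ))) — the unnormalized
  convention with range [0, √2]. Draws come from the untruncated mixture;
  N defaults to 100,000 (s.e. ≈ 0.3%) for single calls and 10,000 inside
  study runs, where it only feeds diagnostics. Sampling noise can push
  the radicand slightly negative when f ≈ h; the estimate is clamped at 0.
* **Capped MSE**: τ̂₂ estimates are ceilinged at 100 ns before averaging
  (τ̂₂ − τ₂)², reported in ns² — the field's way of summarizing error
  without letting a few runaway estimates dominate.
* **Ratio quantiles** of τ̂₂/τ₂ use linear interpolation between order
  statistics (numpy's default); at 10³–10⁴ samples the convention is
  immaterial.

## Synthetic data and the simulation study

`simulate_photons` draws i.i.d. delay times from the mixture (component
choice by a uniform draw against c, then an exponential of the chosen
lifetime); `bin_photons` bins them into half-open intervals
[δ(j−1), δj), discarding photons at or beyond δm — the matching assumption
to the window-normalized likelihood. The default study grid: τ₁ = 1500 ps,
c ∈ {0.60, 0.75, 0.90}, τ₂ = k·τ₁ for
k ∈ {0.5, 0.8, 0.9, 0.95, 0.99, 1.01, 1.05, 1.1, 1.2, 2.0}, δ = 50 ps,
50 photons per dataset, 1000 replicates per configuration. The bin count
m = 200 (a 10 ns window) is a package choice: it mirrors typical
~12.5 ns-repetition TCSPC acquisition windows and exceeds three times the
largest τ₂ on the grid, so truncation is mild; it is configurable and
recorded in outputs. Per-dataset randomness derives from the master seed
through counter-based `SeedSequence` keys (configuration index, replicate
index, stream), so any subset of the grid reproduces bit-identically
regardless of execution order.

The generator emulates ideal TCSPC photon statistics only. It does not
model the instrument response function (timing jitter of order 5% of a
lifetime, negligible against 50-photon noise and deliberately out of
scope), background or afterpulsing, detector dead time, or pile-up —
passing tests therefore demonstrate estimator behavior under the model's
own assumptions, not robustness to those artifacts.

Problem sizes used by the shipped checks, chosen to keep a laptop run in
minutes: the test suite runs the grid at 100 replicates per configuration
(3,000 datasets) and the acceptance script at 200 (6,000 datasets);
failure counts are reported scaled to the full 30,000-dataset design.

## Known limitations

* **The gamma conversion is biased, by construction.** Its large-sample
  limit is the KL projection of the binned biexponential onto the gamma
  family, whose moments do not equal the truth's; e.g. at
  (c = 0.75, τ₁ = 1500, τ₂ = 750) the fitted median of τ̂₂/τ₂ stabilizes
  near 1.37 as n grows rather than approaching 1 (one shipped test
  documents exactly this and fails intentionally). The estimator's value
  is variance control at tiny n — at 50 photons its capped MSE is ~25×
  smaller than the direct fit's — not asymptotic correctness. With
  thousands of photons per curve, fit the biexponential directly.
* Failure proportions and extreme-quantile magnitudes are properties of
  the optimizer protocol as much as of the likelihood; other Nelder–Mead
  termination rules or coordinate schemes find different local optima on
  these near-degenerate surfaces (measured during development and
  deliberately pinned down by the protocol above).
* Fits require at least 2 photons spread over at least 2 bins; mixtures
  with more than two components are supported only through the numeric
  moment solver, not the likelihood fits.
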