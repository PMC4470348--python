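# Methods

## Model

A cell's genome is represented as the unit interval with all chromosomes
concatenated; chromosome ends become pseudo-breaks, accounted inside the
baseline break count rather than tracked as special positions. Alkaline
unwinding opens a region of relative length `μ` to each side of every
break, and overlapping regions from neighbouring breaks interfere, so
with break positions `0 < z₁ ≤ … ≤ z_m < 1` (boundary points `z₀ = 0`,
`z_{m+1} = 1` added) the remaining double-stranded fraction is

    L = Σ_{k=0..m} max(z_{k+1} − z_k − 2μ, 0).

Boundary gaps receive the same `(Δ − 2μ)₊` treatment as internal gaps —
that is exactly what the concatenation trick buys. Tied break positions
are legal; a zero-length gap contributes nothing.

For `m` breaks placed i.i.d. uniformly, the `m + 1` spacings are
exchangeable with marginal density `m(1 − x)^{m−1}`, giving the
conditional expectation

    E(L | m) = (m + 1) ∫_{2μ}^{1} (x − 2μ) m (1 − x)^{m−1} dx
             = (1 − 2μ)^{m+1}      (0 when 2μ ≥ 1).

Treating breaks as a baseline count `D⁰` plus an induced count `γd`
proportional to X-ray dose `d`, and assuming cell-to-cell variation of
`(D⁰, γ, μ)` is small enough that the population expectation can be
written with effective values, the relative fluorescence intensity is

    P(d) = B + (1 − B)(1 − 2μ_eff)^(D⁰_eff + γ_eff d)
         = B + (P₀ − B) e^(−βd),

with `P₀ = B + (1 − B)(1 − 2μ_eff)^(D⁰_eff)` and
`β = −γ_eff ln(1 − 2μ_eff)`. The exponent is deliberately allowed to be
non-integer (effective values are population summaries, not per-cell
counts); the strictly integer-`m` closed form is kept as a separate
function because its derivation is order-statistics-based. The `μ_eff = 0`
limit of the reparameterisation returns `(P₀, β) = (1, 0)` to preserve
continuity; `2μ_eff ≥ 1` is rejected because `β` would be infinite.

Inversions: `d = −(1/β) ln((P − B)/(P₀ − B))` and the dose-equivalent
total damage `D_tot = (D⁰_eff + γ_eff d) μ_eff = −(1/β) ln((P − B)/(1 − B))`,
which is computable from `(B, β)` alone — `γ_eff` and `μ_eff` never need
to be separated. Intensities outside the model range raise a typed
domain error; clamping would silently fabricate dose values. Domain
checks on `P ≤ P₀` (and `P ≤ 1`) carry a 1e-12 relative slack so that
round-tripping a model value through floating point never spuriously
fails.

## Simulator

The simulator is the brute-force counterpart of the closed forms: per
cell it draws `(D⁰, γ, μ)` from declarative distributions (point mass,
truncated normal, lognormal, gamma, uniform), derives a total break
count, scatters internal breaks uniformly, and averages
`I = B + (1 − B)·mean(L_i)`. The per-cell fluorescence scale `c` cancels
in the normalised intensity and is kept only for completeness.

The break-count law is not part of the model's assumptions beyond
proportionality, so two options exist: the default deterministic
`round(D⁰ + γd)` and a `poisson` mode `round(D⁰) + Poisson(γd)`. With
point-mass parameter distributions and the deterministic law, the
simulated intensity converges to the closed form at the Monte Carlo
`1/√N` rate; with dispersed distributions it deviates — by Jensen's
inequality `E[(1 − 2μ)^{m+1}]` exceeds the closed form at the mean `μ` —
and the test-suite asserts that the simulator *resolves* this deviation
rather than hiding it. No analytic bound on the effective-value
approximation error is attempted.

## Fitting

The background `B` is a property of the dye/DNA chemistry, hence shared
across donors; each donor `k` contributes `(P₀_k, β_k)`. The joint
objective is the unweighted sum of squares of the replicate means
`P̄_jk`; minimising over every individual replicate instead yields the
same minimiser on balanced designs (the per-cell residual decomposes
into mean residual plus a parameter-free within-cell variance), and both
objectives are implemented so the equivalence can be checked numerically.

Optimisation is Levenberg–Marquardt (`scipy.optimize.least_squares`,
`method="lm"`, analytic Jacobian; trust-region-reflective fallback when
residuals are fewer than parameters). The parameterisation is
unconstrained; soft bound violations (`B ∉ [0,1)`, `P₀ > 1`, `β < 0`,
`P₀ < B`) are reported as flags, never clamped. Tolerances:
`ftol = xtol = 1e-12`, `gtol = 1e-10`, at most 500 iterations' worth of
function evaluations; all recorded in the result. Starting values (the
choice was open): `B₀ = 0.9 ×` the smallest observed mean, `P₀` from each
donor's lowest-dose mean, `β` from a log-linear regression of
`(P̄ − B₀)` on dose over that donor's cells above `B₀` — cheap,
scale-aware, inside the feasible region. Degenerate inputs (fewer than
three distinct doses; all intensities identical, which makes `β`
unidentifiable; all means identical, which makes `SS_tot = 0`) raise
typed errors. Goodness of fit is `R² = 1 − SS_err/SS_tot` with `SS_tot`
taken over the replicate means around their grand mean.

## Bootstrap

Uncertainty uses the within-cell bootstrap matching the triplicate
design: each resample redraws, for every (dose, donor) cell, the same
number of intensities from that cell's observed replicates with
replacement, then refits (warm-started at the original estimate, which
changes nothing statistically and cuts the refit cost to a few
iterations). Intervals are percentile at the requested level (default
95%, default 10 000 resamples); the reported `±` half-widths are
percentile half-widths and labelled as such. BCa intervals are *not*
offered: with three replicates per cell there is no well-defined
jackknife unit that would make the acceleration estimate meaningful.
Non-converged refits are counted, warned about, and excluded from the
percentiles. Missing replicates are tolerated: means use whatever
replicates exist and resampling draws from the available set.

A known, quantifiable limitation: resampling `n = 3` values per cell
makes the plug-in standard error of a cell mean too small by the factor
`√((n−1)/n) = √(2/3) ≈ 0.82`, so nominal 95% percentile intervals
undercover — measured coverage in the reduced-scale simulation below is
≈ 0.88 for the shared background and ≈ 0.83 for per-donor parameters.
This is inherent to the resampling scheme the assay's triplicate design
admits, and the package reports it rather than correcting for it.

## Synthetic experiments

The generator's defaults reproduce the reference calibration design:
11 donors with the published `(P₀, β)` per-donor values, shared
`B = 0.122`, doses 0, 0.3, 1, 1.9, 3.8, 7.5, 14.9 Gy, three replicates.
Noise is additive, homoscedastic Gaussian on the intensity scale with
default sd 0.005 — the instrument's replicate noise is not published, and
this value makes bootstrap CI widths comparable to the reference
per-donor uncertainties (≈ 0.01–0.08). Generated intensities are floored
at 1e-6 so the positivity invariant of downstream validation always
holds. What the generator does **not** emulate: dose-dependent or
multiplicative noise, plate/batch effects, instrument drift, and donor
covariates — so passing recovery tests demonstrates correctness of the
estimation machinery under the stated error model, not robustness to
real-instrument artefacts.

## Problem sizes used in the test-suite

Monte Carlo cross-checks of the conditional expectation use 10⁵
configurations per (m, μ) grid point; population simulations use
10³–5·10⁴ cells; the recovery experiments use the full 231-observation
reference design; the bootstrap coverage simulation uses 200 repeated
experiments × 500 resamples. These sizes put Monte Carlo error well
below the assertion tolerances while keeping the default run fast.

## Limitations

- Chromatin structure is ignored: breaks are uniform along the genome,
  appropriate for X-ray damage but not for agents with sequence or
  chromatin-state preference.
- The effective-value approximation is unquantified; the simulator can
  probe it empirically but no error bound is provided.
- The fit is unweighted; heteroscedastic or donor-random-effect models
  are out of scope.
- Bootstrap intervals undercover at triplicate depth (see above).
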