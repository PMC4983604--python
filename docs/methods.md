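# Methods

This note documents the statistical machinery in `richrates`: the models
and their assumptions, the estimators and their numerical details, what
the simulators emulate, and the design choices made where more than one
convention exists.

## The comparative question and the data

The package analyses a clade-level table: for each of 15 plethodontid
salamander clades, the natural log of species richness, the crown age
(My), three rates of trait evolution (climatic niche, body size, body
shape; each a Brownian-motion σ² estimated from principal-component
scores), the Pybus–Harvey γ summarizing diversification slowdown within
the clade, and the number of species sampled when the rates were
estimated. The per-clade rates and γ values are *inputs*: the raw
species-level morphometric and climate data, and the within-clade
phylogenies behind γ, are not redistributable, so the package estimates
those quantities only for data you supply (or simulate). Sampling-effort
checks (squared Pearson correlations between the sampled-species counts,
and between counts and integer richness recovered as
`round(exp(ln_richness))`) use the raw, untransformed counts — that
choice reproduces the dataset's published summary correlations exactly
(0.89 / 0.79 / 0.68 at two decimals), which settles an ambiguity about
whether they were computed on logs.

## Phylogenies, covariance, branching times

Trees are rooted, with branch lengths in My, parsed from Newick or NEXUS
(TRANSLATE tables, quoted labels and bracket comments supported) via
dendropy and held in a parent-pointer array structure. Under Brownian
motion the expected tip covariance is `C[i,j] =` shared root-to-MRCA
path length, `C[i,i] =` root-to-tip depth; this matrix drives both GLS
and σ² estimation. Pagel's λ multiplies off-diagonals only: λ = 1 is the
Brownian covariance, λ = 0 a star tree with the original depths.

Ultrametricity is checked as `max |tip depth − mean| / mean ≤ rtol` with
`rtol = 1e-6` by default — rate-smoothed supplementary trees are near-
but not bit-ultrametric, so an exact check would be wrong; the tolerance
is configurable and violations name the offending tip. Branching times
are internal-node ages; a k-way polytomy contributes k − 1 coincident
ages (zero-length internodes), which keeps γ defined on imperfectly
resolved trees. Branch lengths are used as given; no rescaling.

## The γ statistic

With internode intervals `g_k` (duration with k lineages, k = 2..n),
`T = Σ k·g_k`, `T_i = Σ_{k≤i} k·g_k`:

    γ = [ mean_{i=2..n-1}(T_i) − T/2 ] / [ T · sqrt(1/(12(n−2))) ]

γ is invariant to uniform time rescaling and asymptotically standard
normal under a constant-rate pure-birth process; negative values mean
branching concentrated toward the root (in interval terms: `g_n` large,
early intervals small). The implementation is cross-checked against a
reverse-accumulation variant to 1e-9 and against `ape::gammaStat`.

## Brownian rates

For tip values x and covariance C, the ML estimates are
`μ̂ = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹x` and `σ̂² = (x−μ̂1)ᵀC⁻¹(x−μ̂1)/n`; REML (divide by
n − 1) is available but ML is the default, matching how the packaged
rates were originally estimated. On a star tree this reduces to
`Σ(xᵢ−x̄)²/(n·t)`. Multi-trait data (e.g. several PCs) yield one σ² per
trait; the single multivariate rate is their **sum** by default — under
a shared tree the multi-rate Brownian log-likelihood separates by
trait, making the summed rate the natural scalar — with the mean as a
recorded, configurable alternative, since the original publications do
not state the combination formula. PCA is provided with an explicit
covariance-vs-correlation switch (correlation recommended for climate
variables on mixed scales, covariance for log-scale morphometrics);
neither path claims to reproduce the original unpublished PC scores.
Solves use Cholesky factorization; a singular covariance (coincident
tips) raises with advice to jitter zero-length branches.

## PGLS with ML λ

For fixed λ the GLS solution is closed-form (see the module docstring
for the formulas); the log-likelihood includes all multivariate-normal
constants so AIC is comparable across implementations. λ is profiled on
[1e-7, 1] by bounded Brent searches started from overlapping windows
around {0.1, 0.5, 0.9} (small-n profile likelihoods can be multimodal),
convergence tolerance 1e-8, with the boundary values checked explicitly;
estimates at a bound are flagged `boundary`, and a star-tree covariance
(λ has no effect) returns the lower bound flagged `uninformative` rather
than raising. κ and δ transforms are out of scope (fixed at 1).

Reported per fit: β with standard errors and t tests (using the unbiased
residual variance RSS/(n−p)), r² = 1 − RSS/TSS with TSS taken around the
GLS-weighted mean, the whole-model F test with (p−1, n−p) df as the
single model P value (per-coefficient t tests are also available), the
ML log-likelihood, and AIC = −2logL + 2k with
**k = #coefficients + 1 (residual variance) + 1 if λ was estimated**.
The λ-counting is configurable (`count_lambda_in_k`) because published
AIC values from different PGLS implementations differ in this
convention; absent a reference tree to calibrate against, the default
counts λ. ΔAIC ≥ 4 between models of the same response is flagged as a
substantially better fit, boundary inclusive; ties and boundary λ̂ are
reported, never silently resolved.

## Simulators

All generators are pure functions of their parameters and a seed (one
`numpy` Generator per call, consumed in documented order), so outputs
are bit-reproducible across platforms.

- **Yule trees**: crown-conditioned pure birth; the waiting time with k
  lineages is Exponential(k·rate) including the final interval, so
  internode intervals follow the null under which γ is standard normal.
- **Brownian traits**: tips drawn from N(mean, σ²·C_λ) via Cholesky
  (with a 1e-12-relative jitter for numerical rank).
- **Clade tables**: a Yule backbone; climate/size/shape rates drawn
  lognormal; `ln richness = β₀ + β₁·(driver rate) + BM residual` with
  residual SD `noise_sd` at the tips and signal λ; integer richness is
  `round(exp(·))` (so the table is self-consistent with the recovery
  rule) and γ is drawn Normal per clade. Defaults emulate the real
  table: 15 clades, birth rate 0.033/My (≈15 lineages in 61 My),
  β = (2.33, 4.76) and residual SD 0.6 (the OLS fit of the packaged
  table), rates lognormal around 0.09, γ ~ N(−1.8, 0.7²).

What the simulations do *not* emulate: trait-dependent diversification,
incomplete and nonrandom species sampling within clades, estimation
error in the input rates and γ, and topology/branch-length uncertainty.
Passing recovery tests therefore shows the estimators are correct under
their own model, not that the biological conclusions are robust to those
real-data complications.

## The backbone tree fixture

The packaged NEXUS tree is a synthetic stand-in: topology from published
plethodontid relationships (two subfamilies; Spelerpinae sister to the
tropical bolitoglossines; eastern vs. western *Plethodon*; *Aneides*
with *Desmognathus* + *Phaeognathus*), node ages invented around a 61-My
root. Grid results on it are internally valid demonstrations of the
pipeline, not replications of published tree-dependent estimates —
which is also why the end-to-end check asserts well-formedness and
internal consistency of the comparison table rather than specific
published r²/AIC values.

## Problem sizes and tolerances

The validation suite uses: 2,000 fifty-tip Yule trees for the γ null
(mean within 0.1 of 0, SD within 0.1 of 1); 200-tip trees × 200 traits
for σ² recovery (mean within 5%); 100 fits on 200-tip trees for λ
recovery (median λ̂ ≥ 0.9 from λ = 1 data); 200 synthetic 15-clade
datasets for slope CI coverage (≥ 90% nominal 95% coverage — slightly
anticonservative at n = 15 with λ estimated, a known small-sample
property of PGLS); exact-identity checks (OLS agreement, star-tree
closed form, explicit-inversion β) at 1e-10. Hand-checkable anchor:
γ(g₂ = g₃ = 1) = −0.34641.

## Known limitations

- n = 15 is small for joint (β, λ) estimation; λ̂ frequently hits 0 or 1
  and should be read through its boundary flag.
- The F-test model P assumes the fixed-λ GLS distribution theory;
  estimating λ makes it approximate (as in standard PGLS practice).
- Polytomy handling assumes hard polytomies (simultaneous splits).
- `run_richness_models` refits λ per model, so AICs within a response
  group compare models that may sit at different λ̂ values — the standard
  convention, but worth remembering when ΔAIC is near a decision
  threshold.
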