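# Methods

## Model

Let `y_t` (length `n_y`) be observed indicators of `n_η` latent variables
`η_t` through a linear factor model `y_t = τ + Λ η_t + ε_t` with
measurement invariance over time (and, in the panel setting, over the
within/between levels). The latent process is a stationary lag-1 VAR,
`η_t = B η_{t−1} + ζ_t`, whose innovation covariance is parameterized as
a Gaussian graphical model,

```
Σ(ζ) = Δ(ζ) (I − Ω(ζ))⁻¹ Δ(ζ),
```

with `Ω` a symmetric zero-diagonal matrix of partial correlations and `Δ`
a positive diagonal scaling on the SD scale. The stationary latent
covariance solves the discrete Lyapunov identity
`Σ₀ = B Σ₀ Bᵀ + Σ(ζ)`, computed by the Kronecker/vec linear solve
`vec(Σ₀) = (I⊗I − B⊗B)⁻¹ vec(Σ(ζ))`; lag-k covariances follow the
recursion `Σ_k = B Σ_{k−1}`.

**Time series (ts).** Consecutive occasions are paired into rows
`(y_{t}, y_{t+1})`; the first occasion of every block (e.g. day) carries
missing lead values so pairs never straddle block boundaries. The stacked
covariance is Toeplitz: lag-0 block `Λ Σ₀ Λᵀ + Θ`, lag-1 block
`Λ B Σ₀ Λᵀ`, and a lead block that is *saturated with its own unique
parameters* (`μ*`, `Σ*` via a Cholesky factor) — the rows duplicate data,
and counting the lead block as free parameters keeps the degrees of
freedom honest. Latent means are fixed to zero (single-subject
identification). The pairing device means the FIML value is a composite
likelihood rather than the exact joint likelihood of the series; the
exact single-observation treatment of the full vectorized series is
deliberately out of scope.

**Panel.** For `n_t ≥ 3` waves, the per-subject stacked covariance is
block Toeplitz with block `(s, t)`

```
Λ Σ(η)_between Λᵀ + Θ_between + Λ Σ_{|s−t|} Λᵀ (+ Θ_within iff s = t),
```

where the between-subject latent covariance is itself a GGM (the
between-subject network) and `Σ_k` is the stationary within GVAR
structure. The mean repeats `τ` per wave; latent stationary means are
fixed to zero by default because `τ` and latent means are not jointly
identified without further constraints. Indicators absent at a wave are
removed from the stacked mean/covariance by row/column deletion.

A degenerate cross-sectional member (observed-variable GGM with free
means) is included; it is the workhorse for distributional calibration
tests because single fits cost milliseconds.

## Estimation

The discrepancy minimized is
`F = tr(S Σ⁻¹) + (z̄−μ)ᵀ Σ⁻¹ (z̄−μ) + ln|Σ|` (complete data), or its
FIML form — the same expression per missingness-pattern group, weighted
by `n_i/n`, with `S_i = 0` for singleton groups. Sample covariances use
divisor `n`, and the χ² statistic is `n (F̂_model − F̂_saturated)`; this
pair of conventions reproduces the printed RMSEA back-calculations of
both example analyses exactly. The saturated value is the closed form
`p + ln|S̄|` for complete data and is obtained by EM for the unstructured
multivariate normal under missingness otherwise.

Optimization is L-BFGS-B on an unconstrained reparameterization: `log`
for scalings, residual SDs and Cholesky diagonals, `atanh` for partial
correlations, raw coordinates for loadings, intercepts and temporal
coefficients. Stationarity (spectral radius `< 1 − 1e−6`) and positive
definiteness (Cholesky with eigenvalue tolerance `1e−10`) are checked
inside the objective; violations return a large penalty value, and a fit
that terminates in the penalty region is flagged `converged = False` with
a typed reason rather than raising, so simulation studies can tally
success rates. Convergence tolerance is `1e−12` (relative) on the fit
value. Default starting values are deterministic: loadings 1, empty
networks, `B = 0.1·I`, intercepts/means at sample means, scalings and
residual SDs derived from sample variances, and the saturated lead block
at the sample moments.

Gradients are exact in the moment structure — `∂F/∂(μ, Σ)` is analytic —
combined with a central-difference Jacobian of the parameter → (μ, Σ)
map. Parameters that enter only the mean (intercepts, saturated means)
and the saturated Cholesky block have fully analytic derivatives, which
removes roughly two-thirds of the finite differencing for latent
time-series models.

Standard errors come from the inverse of the expected (Fisher)
information `(n/2) H` with
`H_ij = Σ_g w_g [tr(Σ_g⁻¹ ∂Σ_i Σ_g⁻¹ ∂Σ_j) + 2 ∂μ_iᵀ Σ_g⁻¹ ∂μ_j]`,
evaluated at the estimates; a fully numerical observed-information
Hessian is available as an option. The expected form is positive
semidefinite by construction and two orders of magnitude cheaper, which
matters because the model search recomputes information matrices at every
step; a Monte-Carlo calibration test (empirical SD of estimates vs mean
reported SE, ratio within [0.8, 1.2]) guards the choice. RMSEA is
`√(max(0, χ²−df)/(df·n))` with a 95% interval from noncentral-χ² root
finding. Incremental indices use an independence baseline (free means and
variances, zero covariances); the source analyses never state their
baseline, so printed incremental indices are not used as test oracles —
only the χ²/df/RMSEA arithmetic is.

Temporal coefficients are standardized for display to partial directed
correlations, `PDC_ij = b_ij / √(σ_ii κ_jj + b_ij²)` with `σ` the
innovation covariance and `κ = σ⁻¹` (Wild et al. 2010); the formula is
sign-preserving and bounded in (−1, 1).

## Model search

The pipeline mirrors the published workflow: (1) fit the fully connected
model; (2) fix to zero all network edges not significant at α —
optionally after Bonferroni, Holm or Benjamini–Hochberg adjustment, with
the adjustment family being one network matrix (temporal,
contemporaneous, between are separate families, mirroring per-network
reporting) — and refit; (3) stepwise search. Modification indices are
score tests: `MI = (n/2) g_c² / s_cc`, where `g_c` is the fit-function
gradient at the constrained edge and `s_cc` the Schur complement of the
expected information after profiling out the free parameters. Full
curvature is used rather than the diagonal because the diagonal
approximation misstates the χ² drop badly when parameters are correlated.
`stepup` frees the strongest significant MI while BIC improves;
`modelsearch` additionally considers fixing currently non-significant
free edges, refits every candidate, and accepts the single change with
the best BIC per iteration (ties prefer removal, then lexicographic
order, for determinism), stopping when no candidate improves BIC — so the
accepted-BIC sequence is strictly decreasing. Previously pruned edges are
reconsidered (symmetric neighborhood). The 24-variant grid
(3 strategies × 4 adjustments × 2 α) is pure settings.

## Bootstrap

Case-drop bootstrap: each replicate removes `⌈proportion·n⌉` cases —
a contiguous occasion block starting at a uniform index for time series
(default with wrap-around: a segment truncated at the series end
continues from the start; truncate-only is available), or a uniform
subject subset for panels — reruns the full pipeline, and tallies signed
edge inclusions plus a co-inclusion matrix. Blocks are split at the
removal seam so no pair straddles the gap. Failed replicates are counted
and excluded, not imputed or retried. Replicate seeds derive from the
master seed via seed sequences, so summaries are bit-reproducible and
mergeable (count additivity).

## Synthetic data

`simulate_ts` draws the latent series from the stationary distribution,
iterates `η_t = B η_{t−1} + ζ_t`, discards a 100-occasion burn-in, and
applies the measurement model with independent Gaussian residuals.
`simulate_panel` draws subject means from the between-subject model
(latent means from the between GGM, residual means from the between
residuals) and within deviations from the stationary GVAR, the first wave
exactly from the stationary distribution (no burn-in needed). Both are
deterministic per seed; simulated data are complete (missingness patterns
are an estimation concern, injected by the time-series pairing).

Bundled generating parameter sets:

* full-scale stand-ins with the published example dimensions —
  5 factors / 14 indicators (time series) and 6 factors / 22 indicators /
  3 waves (panel). The network matrices use the published standardized
  estimates verbatim (temporal entries taken as raw coefficients on the
  standardized latent scale, since the raw matrices are not published);
  loadings (0.7–1.0), intercepts (scale midpoints: 4 on 7-point items,
  3 on 5-point items), scalings and residual SDs are stand-in values
  chosen once for realistic variance decompositions and frozen in source.
* small observed-variable models (4-node GVAR; 4-node / 3-wave panel)
  used for study grids and calibration, where a full search pipeline
  costs seconds rather than minutes.

What the simulators deliberately do **not** emulate: ordinal 5/7-point
response scales (data are continuous Gaussian), item-level missingness,
non-stationarity or trends, and subject heterogeneity in network
parameters. Passing recovery tests therefore demonstrate correctness of
the estimator under its own assumptions, not robustness to their
violation.

## Evaluation metrics and study sizes

`edge_metrics` compares searchable network entries of an estimated
structure against the generating one: sensitivity (true edges recovered),
specificity (true absences kept absent), Pearson correlation between true
and estimated weights over all searchable entries, and a success flag
(converged estimation). An edge counts as included when its weight is
nonzero — pruned edges are fixed at exactly zero.

The study harness shares work within a replicate: one saturated fit per
dataset, one prune+refit per (adjustment, α) pair, searches on top —
a paired design across all 24 variants. The packaged test grids run the
full 24-variant battery on the small observed-variable models at the
smallest sample sizes of the published grids (50 occasions / 500
subjects) with 20 (time series) and 10 (panel) replicates per cell, and
the sensitivity-vs-n check uses 12 replicates across n ∈ {50, 100, 250,
500} — sizes chosen so the whole battery completes in minutes on one
core. Full-scale latent search grids are supported through the same
`SimConfig` interface but cost minutes per pipeline.

## Known limitations

* The ts likelihood is a pairwise composite (Toeplitz device), so its χ²
  does not test stationarity constraints the way the panel χ² does.
* Expected-information SEs assume the model is (approximately) correct;
  no robust/sandwich option.
* Only lag-1 dynamics; lag-k covariances are derived quantities.
* No regularized estimation, no random effects on network parameters, no
  multi-group or measurement-invariance machinery.
* Residuals are modeled as variances only (the diagonal case of the
  triangular factorization, parameterized on the SD scale so variances
  stay nonnegative); correlated residuals are not supported.
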