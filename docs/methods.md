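# Methods

## Model and estimators

A sample is a vector of counts `N = (N₁, …, N_k) ~ Mult(n, p)` over `k ≥ 2`
*ordered* categories; `p̂ = N/n` is the maximum-likelihood estimator of `p`.
The package studies four plug-in functionals `H(p̂)`: Shannon, Tsallis-q
(q ≠ 1), Rényi-q (q > 0, q ≠ 1), and the discrete Fisher information measure
`F₀ Σ_{ℓ<k} (√p_{ℓ+1} − √p_ℓ)²`. Category order is part of the data model
because Fisher information reads adjacency off it; nothing is ever sorted,
and category collapsing only merges contiguous blocks.

Conventions: natural logarithms internally (raw entropies in nats);
`0·log 0 := 0` and `0^q := 0` for q > 0. Normalized variants divide
Shannon/Rényi by `log k` and multiply Tsallis by `(q−1)/(1−k^{1−q})`; these
lie in [0, 1], equal 1 exactly at the uniform distribution, and are
independent of the logarithm base — which is why normalized values are the
ones reported and compared across different `k`. The Fisher functional is
used exactly as defined; note it is *not* bounded by 1 for every `p` (an
interior point mass gives 2F₀), and no clamping is applied.

## Asymptotic laws

`√n (p̂ − p) → N(0, Σ_p)` with `Σ_p = D_p − p pᵀ` (diagonal `p_ℓ(1−p_ℓ)`,
off-diagonal `−p_ℓ p_j`; rows sum to zero, PSD of rank ≤ k−1). The
multivariate delta method propagates the per-category functions through
their gradient matrix `B`, giving limit covariance `B Σ_p Bᵀ`. For Shannon,
Tsallis and Rényi `B` is diagonal, and the scalar variance reduces to the
contraction

```
Var ≈ (1/n) [ Σ p_ℓ a_ℓ² − (Σ p_ℓ a_ℓ)² ]
```

with `a_ℓ = log p_ℓ + 1` (Shannon), `(1 − q p_ℓ^{q−1})/(q−1)` (Tsallis), and
`q p_ℓ^{q−1}` (the Rényi power sum). The implementation evaluates this
contraction with the *p-weighted* terms so that zero-cell limits are taken
before any division; an independent test route checks it against the full
matrix product and against the entry-wise closed forms.

**Rényi** is special: the power sum `S = Σ p̂^q` is asymptotically
`N(μ*, σ*²)` with `μ* = Σ p^q`, `σ*² = (q²/n)[Σ p^{2q−1} − (Σ p^q)²]`, so
`H = log(S)/(1−q)` follows the law of the logarithm of the absolute value of
a normal variate. The density is derived by change of variables (with the
`|S|` reflection kernel, which makes it an exact density; the reflection
term is numerically negligible whenever `μ*/σ*` is large), and the CDF
handles both monotonicity branches (q < 1 and q > 1). Normalized laws are
obtained by the exact scaling `f_norm(x) = log k · f(x log k)`.

**Variance conventions.**

- `renyi_variance_convention="power_sum"` (default): the `variance` field of
  a Rényi law stores `σ*²`, the variance of the power sum. This is the
  convention under which the reference worked-example variance and p-value
  tables reproduce, so it is the default; the two-sample test then compares
  normalized Rényi *means* using power-sum variances. The statistically
  natural alternative `"delta"` stores `σ*²/((1−q)² μ*²)` (divided by
  `(log k)²` if normalized), the delta-method variance of the entropy
  itself; `EntropyResults.bse` always reports the entropy-scale standard
  error via this transform.
- `fisher_variance_mode="delta"` (default): `gᵀ Σ_p g / n` with `g` the
  scalar gradient of the Fisher functional (computed through p-weighted
  terms, finite at zero cells). Monte-Carlo calibration (10⁴ replicates,
  linear profile, k=6, n=6000) confirms this variance within a few percent.
  `"paper"` transcribes a published closed form that differs from the exact
  contraction in its last-row terms (its final diagonal term carries an
  asymmetric `(1 − p_{k−1})` factor); it is retained for comparison only and
  is *not* used by default, because calibration contradicts it. A test
  verifies the two coincide exactly when `p_{k−1} = p_k`, where the
  discrepant terms vanish.

**Zero probabilities.** Variance terms whose `p_ℓ → 0` limit is finite are
evaluated at that limit (structural zeros contribute nothing: a category
with `p_ℓ = 0` never receives counts, so even terms with a nonzero formal
limit, as at q = 1/2, contribute zero variance in truth). Terms that blow up
as `p_ℓ → 0` — those with exponent `2q − 1 < 0` — are handled by a zero
floor (default 1e-10): categories below it are excluded from the variance
sums with a `RuntimeWarning`. With the floor disabled, strictly positive
cells are evaluated literally (producing a finite but possibly enormous
variance) and exact zeros raise `DegenerateSupportError`. The floor matters
for the one-almost-zero profile, whose `ε₀ = 2.220446e-16` cell would
otherwise dominate the q < 1/2 Rényi variance by a factor `ε₀^{2q−1}`.

Point masses yield degenerate (zero-variance) laws, flagged rather than
erroneous; sampling from them warns and returns constants. All variances
scale exactly as 1/n.

## Two-sample test

`z = |H₁(p̂₁) − H₂(p̂₂)| / √(σ̂₁² + σ̂₂²)`, `p = 2(1 − Φ(z))`, with each
variance evaluated at that sample's own plug-in proportions and `n` (not
pooled). The test is symmetric in its arguments and p is monotone in the
mean separation at fixed variances. Samples may have different `k`
(normalized entropies share a scale) or even different entropy families, in
which case a warning notes that the null is equality of two different
functionals. Both variances zero (two point masses) raises
`DegenerateTestError` rather than fabricating p = 0. No multiple-testing
correction is applied; p-values are raw and printed in scientific notation
below 1e-4. Monte-Carlo calibration under the null (same linear profile in
both arms, k=6, n=6000, 2000 pairs) puts the empirical size at α = 0.05
within [0.03, 0.07]. The Pearson χ² homogeneity test (scipy, no continuity
correction, df = k−1) is included as the classical baseline for equal-k
comparisons.

## Synthetic probability profiles and the validation grid

Three profiles drive the simulation study, chosen to span support shapes:

- **Linear**: `p_ℓ = 2ℓ/(k(k+1))` — strictly increasing, well-conditioned.
- **One-Almost-Zero**: uniform except `p_{k−1} = ε₀` (machine epsilon,
  2.220446e-16 by default, configurable within (0, 2/k)) and
  `p_k = 2/k − ε₀` — probes near-degenerate support.
- **Half-and-Half**: `(1±ε)/k` on each half, `ε ∈ {0.1, 0.3, 0.5, 0.8}` —
  near-uniform for small ε, where entropy estimates are most non-normal.
  Only even `k` is defined; odd `k` raises rather than guessing a split.

The reference grid crosses six functionals (HS, HT½, HT³ᐟ₂, HR⅓, HR⅔, HF)
with the six profile configurations, `k ∈ {6, 24, 120, 720}` and
`n = m·k, m ∈ {10², 10³, 10⁴}`: 432 cells. Per cell, 300 replicate samples
(exact multinomial sampling — never a normal approximation, because tail
cells with `n p_ℓ ≪ 1` matter) are drawn once per `(profile, k, n)` and
shared across the six functionals; child seeds derive deterministically from
the master seed and the cell coordinates, so results are bit-identical
regardless of execution order. The Anderson–Darling sweep tests normality of
the replicate entropies (statsmodels' `normal_ad`; its size was verified at
~1% under the null), applied to raw values since normality is affine
invariant. The Kolmogorov–Smirnov sweep (50 replicates, 5%) tests the
replicate entropies against the law evaluated at the *true* generating `p`
— the fully specified reading of goodness of fit — using the normal law for
HS/HT/HF and the log-power-normal law for Rényi. Degenerate cells (constant
replicates, e.g. Fisher at exactly uniform `p`) are flagged, not crashed.

What these simulations do and do not show: the profiles exercise smooth,
near-degenerate and near-uniform regimes, but all cells are exact
multinomial draws from a known `p` — no overdispersion, dependence between
trials, or misclassification, so passing sweeps validate the asymptotic
algebra, not robustness to real-data violations of the multinomial model.
Because the KS reference uses the true-`p` law including its mean, the sweep
is sensitive to the O((k−1)/2n) finite-sample mean bias of plug-in entropies
near uniform profiles; several near-uniform cells therefore fail KS even
though their *shape* is close to normal. This is expected behaviour of the
fully specified test, not an implementation defect.

## Numerical and design choices

- Seeds are explicit everywhere; no hidden global RNG state.
- The `paper` Fisher variance and the one-almost-zero default `ε₀` are
  configuration values, not hard-wired constants.
- Count-table files are read in file order (never sorted); two-column
  `label,count` with optional header, or a single row of integers; parse
  errors name the offending line.
- Problem sizes used by the shipped checks — 10⁴ replicates for variance
  calibration, 2000 pairs for test size, 10⁶ draws for the Rényi density
  check, 300 replicates per grid cell — were chosen to give Monte-Carlo
  error comfortably below the tolerances asserted (e.g. variance ratios
  within 5%, KS distance 0.005).

## Known limitations

- The plug-in estimator is biased at finite n (downward for Shannon by
  ≈(k−1)/2n near uniform; upward ≈2% for Fisher at the linear k=6, n=6000
  setting); no Miller–Madow or jackknife correction is provided, since the
  distribution theory is for the plain plug-in estimator.
- The two-sample test is asymptotic; no finite-sample correction or exact
  small-n test is offered.
- The Fisher functional's published closed-form variance disagrees with
  both delta-method calibration and Monte-Carlo simulation; its origin is
  unresolved, and only the delta-mode variance should be used for inference.
- k is assumed desk-scale (≤ ~10⁴); no sparse or streaming support.
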