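# Methods

## The testing problem

Given an m × n matrix Y of genomic variables (genes, probe sets, loci) by
observations, with m ≫ n, principal components of Y are routinely used as
estimates of the manifestation of latent variables — cell-cycle phase,
clinical subtype, batch — in the data.  The natural follow-up question is
which variables drive those components.  The obstacle is that the PCs are
functions of the very rows being tested: regressing row y_i on the top-r
right singular vectors V_rᵀ and reading a p-value off the parametric
F(r₁, n−r) distribution is anti-conservative, because even a pure-noise row
contributes to, and therefore correlates with, the fitted components.  This
over-fitting grows as m shrinks and does not vanish at m in the thousands.

## Model

The generative model is a conditional factor model

    Y = B L + E,

where L is an r × n row basis for the latent-variable effect (each row
centered and scaled to unit sample variance), B is m × r with row b_i
quantifying variable i's loading, and E is i.i.d. Gaussian noise.  Rows
with b_i = 0 are the null variables.  Since L is unobserved, the working
model replaces it with the top-r right singular vectors of the row-centered
Y:

    Y = Γ V_rᵀ + E′ ,

and the hypothesis for variable i is H₀: γ_i = 0 (or a subset of its
components, below).

## The association statistic

Each centered row is regressed on the r orthonormal basis rows.  The
statistic is the partial F comparing the full model (all r PCs) with the
reduced model containing only the r₀ adjustment PCs:

    F_i = [(RSS₀ᵢ − RSS₁ᵢ)/r₁] / [RSS₁ᵢ/(n − r)] .

Degrees of freedom are (r₁, n − r) with **no intercept**: after row
centering both the data rows and the PC rows have exactly zero mean, so an
intercept column would carry zero weight while altering the denominator df.
This convention is internal bookkeeping — the jackstraw calibrates the
statistic empirically, so only consistency between observed and null
statistics matters — but it is fixed and documented so results are
reproducible.  Because the design columns are orthonormal, both RSS values
are computed from squared projections; a full model that fits perfectly
(RSS₁ below 10⁻¹² of the row's total sum of squares) yields F = +∞, which
is a legal value ranking above every finite null statistic; a row fit
perfectly by both models (e.g. an all-zero row) yields F = 0.

Subset tests: an `AssociationSpec(r, subset, rotation)` partitions the
(optionally rotated, rotation orthogonal) basis into r₁ tested and r₀
adjustment components.  With r₀ = 0 the reduced model is the zero-mean
null.  Rotations let users test independent components or other linear
combinations; estimating such rotations is out of scope — they are inputs.

## The jackstraw resampling scheme

1. Compute V_rᵀ from the row-centered Y and the m observed statistics F_i.
2. For b = 1..B: choose s rows uniformly without replacement, replace each
   with an independently permuted copy of itself (a fresh permutation per
   row), recompute the SVD of the perturbed matrix Y*, and record the s
   permuted rows' F-statistics against the recomputed top-r basis.
3. Pool all s × B null statistics and set
   p_i = #{F⁰ ≥ F_i} / (sB), ties counting toward the numerator.

Because s ≪ m, the systematic variation — and hence the over-fitting
behavior of the PCA — is preserved in Y*, while the permuted rows are null
by construction: their association with the recomputed PCs is exactly the
over-fitting the test must absorb.  Permutation preserves row means, so Y*
is centered by construction; the engine asserts this rather than
re-centering.

Defaults: s = ⌈0.10 m⌉ (the middle of the range the calibration studies
sweep) and the smallest B with s·B ≥ 10 m null statistics.  For fixed s·B,
smaller s is more accurate but costs more SVDs; larger s is cheaper and at
most mildly conservative, never anti-conservative — the perturbed matrix
contains more null rows than the original, so its PCs over-fit the noise
slightly more.  One PCG64 stream (from `seed`) drives row selection and
permutations, so a single integer reproduces a run bit for bit.  A
`pseudo_count` option switches to (k+1)/(sB+1) for consumers that cannot
accept p = 0; the plain count formula is the default.

The exhaustive variant (s = 1, within-variable nulls: B permutations of
row i alone, p_i from row i's own null statistics) makes the fewest
assumptions and serves as the gold standard; it costs m × B SVDs and is
used as a cross-check, not a default.

## Multiple testing

π₀ is estimated by the λ-grid census π̂₀(λ) = #{p_i > λ}/(m(1−λ)) over
λ = 0.05, 0.10, …, 0.95, smoothed by a cubic polynomial and read off at the
largest λ, truncated into (0, 1].  q-values follow the step-up transform
q_(i) = min_{j≥i} π̂₀ · m · p_(j)/j.  With π₀ fixed at 1 this is exactly
Benjamini–Hochberg, available as a guaranteed-conservative mode.  The
transform is order-preserving but *not* idempotent — re-applying it shrinks
values toward 1 — so q-values are computed once from p-values.

FDR calibration is assessed by comparing the nominal level t of a call set
{q ≤ t} against the realized false-discovery proportion averaged over
simulated studies.  Empirical p-values have resolution 1/(sB) and can be
exactly zero, which makes realized FDP at very strict thresholds run a few
points above nominal (a variable whose statistic clears the entire null
pool reports p = 0 where the truth is merely p < 1/(sB)); the
`pseudo_count` option removes the zeros at the cost of mild
conservativeness.

## The joint null criterion harness

Valid multiple testing requires more than marginal uniformity: the null
p-values of a study must be jointly i.i.d. Uniform(0,1) ("joint null
criterion"), which is what licenses FDR procedures downstream.  The
harness simulates many independent studies, runs a method on each, and
KS-tests the p-values of the *true* null rows (always identified from the
generator's coefficient matrix, never from fitted loadings; for partial
tests the mask is restricted to the tested latents).  Two sidednesses are
computed: two-sided (any deviation) and one-sided with the empirical CDF
above the uniform CDF (anti-conservative skew toward zero — the failure
mode over-fitting produces).  The per-study KS p-values are then
aggregated by a second one-sided KS test, the double KS test; a small
aggregate p-value demonstrates systematic mis-calibration no single
dataset could establish.  The one-sided orientation is unit-tested against
hand-built skewed inputs, since an orientation error would be silent.

The conventional parametric F-test is run through the identical pipeline
as the anti-conservative comparator; it is exposed only in the evaluation
module and is never the shipped default.

## Synthetic data generator

`simulate_study` draws Y = BL + E with:

* latent rows: a dichotomous split (+c for the first n/2 observations, −c
  after, c = √((n−1)/n) giving exactly unit sample variance) or one full
  sine period over the n observations (centered, unit-variance), or
  user-supplied rows;
* coefficients: exactly round(π₀·m) rows are zero, positions uniform
  without replacement; nonzero entries i.i.d. Uniform(0,1) or ±1 signs
  with probability ½;
* noise: i.i.d. Normal(0, noise_sd²), default sd 1.

The 16-scenario grid crosses {dichotomous, sinusoidal} latents ×
{Uniform(0,1), ±1} coefficients × m ∈ {1000, 5000} × π₀ ∈ {0.75, 0.95},
with n = 20 throughout.  Two multi-latent designs support subset and
rank-misspecification studies: a two-latent design (10/10 dichotomous L1,
5-block alternating L2, orthogonal; 100 variables on L1, 60 on L2, 40 on
both) and a five-latent design whose rows are drawn from a randomized
dichotomous pattern, Normal(0,1), Uniform(0,1), Binomial(2,½) and
Normal(0,0.25), each standardized.  For r > 1 the non-null support is
shared across latents with coefficient values independent per (row,
latent), so the null count is exact.  The sinusoid's frequency/phase and
the multi-latent coefficient law (Uniform(0,1), for continuity with the
single-latent scenario) are generator choices; `custom_latents` accepts
alternatives.

A generator self-check pins down what "over-fitting" means quantitatively:
regressing *uncentered* null rows on the fixed true L gives statistics
that are exactly F(r, n−r) (the centered version would instead be
(n−r)/(n−1−r) · F(r, n−1−r), which a 10,000-draw KS test can tell apart),
while the same parametric reference applied against the data's own top PC
is detectably anti-conservative even at m = 10,000.

### What the generator does not emulate

Real expression data have correlated and heteroskedastic noise, heavy
tails, batch structure and missingness; the generator's noise is i.i.d.
Gaussian.  Passing calibration here shows the method corrects PCA
over-fitting under the factor model, not that it is robust to arbitrary
real-data pathologies.  One genuine limitation surfaced by testing: the
pooled empirical null assumes the null statistics are exchangeable across
rows.  When rows have wildly different marginals — e.g. nearly noiseless
two-point signal rows permuted into the null pool alongside Gaussian noise
rows — pooled p-values for the Gaussian rows mis-calibrate and true FDR
can exceed its estimate.  With noise of the same order as the signal (all
scenarios above) this effect is negligible; users with near-deterministic
rows should prefer the exhaustive variant.

## Evaluation scales and numerical choices

Replication counts are scaled for a desk-class machine: 100 studies for
the single-latent headline check, 25 per grid scenario, 50 for the subset,
rank-misspecification and FDR-calibration studies; pass/fail is expressed
as bounds on double-KS p-values rather than point reproduction of any
particular stochastic run.  Other numerical choices: SVD sign
indeterminacy is fixed by flipping each right singular vector so its
largest-magnitude entry is positive (F-statistics are sign-invariant, but
determinism makes results diffable); requested PCs must have singular
values above 10⁻¹² of the largest, refusing numerically degenerate
components; r is capped at n − 2 to keep a residual degree of freedom;
empirical p-values are computed by sorting the pool and binary-searching,
which is O((m + sB) log sB) and agrees exactly with the naive double loop.

## Known limitations

* r is an input; choosing the number of significant PCs is out of scope.
  Over-specifying r̂ moderately is safe (the rank-misspecification study);
  severe under-specification leaves structured residuals and conservative
  but less powerful tests.
* The largest r singular values must be well separated for subset tests;
  near-ties make individual components unstable under resampling.
* Exchangeability of pooled nulls, as above.
* p-values have resolution 1/(sB); FDR analyses needing finer resolution
  should raise B (or s, accepting mild conservativeness).
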