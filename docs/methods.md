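# Methods

This note documents the generative model, the estimators, the defaults
and the numerical choices behind `fdrsim`, and what the simulation does
and does not say about real data.

## The data-generating model

A dataset is a G × 2N log2 expression matrix: N "normal" and N "cancer"
samples (equal group sizes by construction).  The generator composes
seven stages, each driven by its own RNG stream derived from the single
config seed, so that changing one knob (say ψ) perturbs only its own
stage — the block layout, correlation structure and noise realisations
are held fixed.  Identical config + seed reproduces the dataset
bit-for-bit.

1. **Blocks.**  Gene–gene correlation is "clumpy": genes fall into
   independent blocks that emulate pathways or co-regulated modules.
   Sizes are drawn as 1 + Poisson(ξ − 1) — mean exactly ξ, and ξ = 1
   degenerates to independent singleton genes — with the final block
   truncated so sizes sum to G.
2. **Activity.**  Each block is transcriptionally active with
   probability `active_fraction` (default 0.7).  Inactive blocks emit
   zero raw signal in *both* groups; their observed values are pure
   measurement noise.  Activation never switches between groups.
3. **Correlation.**  Per block, a correlation magnitude
   ρ ~ Beta(`rho_a`, `rho_b`) (default Beta(4, 4): mean 0.5, covering
   loosely to strongly correlated modules) and a sign vector with
   round(θ·size) genes negative.  θ is either fixed in [0, 0.5] or
   tent-drawn (0.5 − |x − 0.5|, x ~ U(0,1), i.e. uniform on [0, 0.5]).
   The block correlation matrix is the one-factor form
   C = (1 − ρ)I + ρssᵀ, chosen because it is positive semi-definite for
   any sign pattern and admits O(size · n) sampling
   (X = √(1−ρ)·Z + √ρ·s·F with a per-sample common factor F) instead of
   a Cholesky factorisation.
4. **Baselines.**  Per-gene mean log2 expression μ_g ~ Normal(6, 1.5²)
   and biological sd σ_g ~ Gamma(shape 4, mean 0.5).  These are
   emulation defaults on the scale of log2 microarray intensities, not
   estimates from any particular dataset; all are configurable.
5. **Differential expression.**  A round-half-up fraction ψ of the
   *active* blocks (uniformly chosen) is flagged DE; every gene in a
   flagged block gets |Δ| ~ Gamma(`de_shape`=10, `de_rate`=10) — mean 1
   on the log2 scale (two-fold on average) with a long right tail — and
   an independent fair ±1 direction.  ψ is applied to whole blocks
   because disease is assumed to act on pathways, not isolated genes.
6. **Sampling.**  Active genes are multivariate normal with covariance
   σ_g σ_h C_gh and mean μ_g (+ Δ_g in the cancer group).
7. **Noise.**  Raw intensities S = 2^X observe
   Y = S·exp(H) + E, with H ~ N(0, `mult_sd`² = 0.1²) and
   E ~ N(2, 1²), clipped below at 1 before the final log2.  The clip
   keeps the log finite and emulates a scanner floor.

### Truth bookkeeping

The per-gene truth table records block id, activity, the DE flag and
the signed shift.  Note that the true null proportion is
π = 1 − (DE genes)/G, which equals 1 − ψ only when every block is
active and ψ·(number of blocks) is an integer multiple of the block
structure.  Study-condition runs that compare π̂ against 1 − ψ therefore
set `active_fraction = 1`; the package default of 0.7 keeps both active
and inactive blocks present, which is the more realistic condition for
general use.

## Estimators

**t-tests.**  Classical pooled-variance two-sample t-tests (Welch
available by flag), two-sided.  Pooled is the default because the
generator gives both groups the same per-gene variance.  The two groups
are ordered by sorted label value, making the sign of t invariant to
label relabelling (swapping groups negates t, p unchanged).  Genes with
zero variance in both groups are untestable; they are kept with t = 0,
p = 1 and a flag rather than dropped, because dropping them would
deplete the uniform component and bias λ̂ upward.

**BUM fit.**  f(x) = λ + (1 − λ)αx^(α−1) on (0, 1], fit by maximum
likelihood with both parameters logit-transformed, L-BFGS-B from five
fixed starting points, and a 1e−12 relative tolerance on the objective.
p-values are floored at 1e−12 before the log (two-sided t p-values can
underflow).  Fewer than 100 p-values triggers a warning but still fits.
The reported upper bound on the null proportion is the density at
x = 1, π̂ = λ̂ + (1 − λ̂)α̂.  The model-based FDR at cutoff τ,
π̂τ/(λ̂τ + (1 − λ̂)τ^α̂) capped at 1, is nondecreasing in τ; the cutoff
for a target FDR is the *largest* τ whose model FDR stays at or below
the target, found by bisection to 1e−10 (any monotone root-finder
agreeing to that tolerance is equivalent).  Boundary conventions: τ = 1
when even the full gene list meets the target (target ≥ π̂), τ = 0 when
no positive cutoff does.

**FDP.**  Positives are p ≤ τ (closed threshold).  FDP = FP/(FP + TP),
defined as 0 when nothing is called — the convention under which FDR is
the expectation of FDP.  The default cutoff grid is 50 log-spaced
points from 1e−6 to 1.

**Dispersion variate.**  z = Φ⁻¹(F_t(t; df)) per gene (computed over
all genes, DE included — the summaries describe the whole statistic
ensemble), with the t CDF clamped to [1e−15, 1 − 1e−15].  The
empirical-null central width σ₀ comes from central matching: z-values
histogrammed in 0.1-wide bins on [−2, 2], a least-squares quadratic fit
to log counts of bins with ≥ 5 observations (≥ 5 such bins required),
σ₀ = (−2c₂)^(−1/2) from the fitted curvature; nonnegative curvature is
an estimation failure.  The dispersion variate is A = (σ₀² − 1)/√2, the
second-Hermite coefficient of the empirical null's deviation from
N(0, 1): A > 0 means a widened central peak.  Bin width, window and
count floor are configurable.

**corr.std.**  The sd of Pearson correlations over 50,000 uniformly
sampled distinct gene pairs (all pairs when fewer exist), seeded.
Zero-variance genes are excluded from the sampling frame with a
warning.  For independent genes over n arrays, corr.std ≈ 1/√(n − 1),
which the calibration tests exploit.

**Resampling stability.**  Repeatedly draw n per group without
replacement (independent across resamples, per-resample derived seeds),
run t-tests, fit the BUM model, record the cutoff achieving the target
FDR (default 10%).  Afterwards each resample's model FDR is evaluated
at the pooled *median* cutoff — the "effective FDR at the median
cutoff" — and, when truth is available, the realized FDP there too.
Both are reported because, for real data, whether such an effective FDR
is model-based or truth-based cannot be distinguished; the model-based
number is primary.

## Study conditions and problem sizes

The full factorial design enumerates N ∈ {10, 25, 50, 100} ×
ξ ∈ {1, 5, 10, 50, 100, 250, 500, 1000} × 4 θ scenarios
(θ = 0, 0.1, 0.25, tent) = 128 configurations, with a ψ sub-study at
ψ ∈ {0, 5, 10, 20, 40}% for ξ ∈ {1, (10,) 100} and N = 25.  Gene count
and replicates per configuration are free parameters; the package's
desk-scale default is G = 2000 with 20 replicates for trend testing
(10 in the acceptance script), which makes the whole trend suite run in
a few minutes on one CPU while leaving every qualitative comparison
well resolved.  Trend runs set `active_fraction = 1` so π = 1 − ψ holds
exactly in expectation.

The resampling experiment uses a G = 5000, ψ = 20%, N = 50-per-group
dataset at ξ = 100 — the strongest-correlation level of the ψ
sub-study — because cutoff instability is a correlation phenomenon: at
near-independent ξ the BUM fits are artificially stable and the
experiment shows nothing.

Seeds are fixed constants in tests; grid rows derive per-dataset seeds
from (base seed, configuration index, replicate) via `SeedSequence`
spawn keys, so tables are reproducible and extensible without
re-running earlier rows.

## What the simulation does and does not capture

It captures: clumpy correlation with negative-correlation fractions,
active/inactive transcription, block-wise differential expression with
realistic fold-change spread, and additive + multiplicative raw-scale
noise with a detection floor.

It does not capture: probe-level or image-level artifacts,
normalization residuals, batch effects, heavy-tailed or skewed
biological variation, gene-length or intensity-dependent biases,
survival outcomes, or blocks that switch activation between groups.
Passing trend tests therefore demonstrate the estimators' behaviour
under the stated generative model, not performance guarantees on any
particular real dataset — on real data the same qualitative forces
(sample size, correlation, DEG proportion) apply, but the magnitudes
of variability are typically larger than the simulation's.

## Known limitations and open choices

- The mean-Â-versus-ψ trend is asserted on the independent-gene (ξ = 1)
  series plus a pooled endpoint comparison: at ξ = 100 the
  central-matching Â carries Monte-Carlo noise of sd ≈ 0.1 per
  configuration, which 20 replicates cannot resolve into a strict
  five-point monotone ordering.
- The anticorrelation between α̂ and λ̂ across replicate fits follows
  from likelihood-area conservation; its magnitude shrinks with the
  biological sample size N (which changes the p-value distribution),
  not with the number of p-values fit (the joint-MLE correlation is
  asymptotically invariant to that).
- The block-size law, per-block correlation distribution, activity
  probability and noise defaults are explicit stand-ins chosen here;
  they are configurable and documented above rather than inherited from
  any measured dataset.
- FDP at zero discoveries is 0 by convention; analyses that prefer the
  undefined-FDP convention should filter on `tp + fp > 0` from the
  recorded confusion counts.
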