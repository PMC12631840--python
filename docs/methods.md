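# Methods

## Data model

All stages operate on four containers: a **beta matrix** (CpG × sample,
values in [0, 1], missing values allowed), a **reference matrix**
(marker CpG × cell type, the per-type mean betas, no missing values), a
**fraction matrix** (sample × cell type, non-negative, rows summing to 1
for full panels), and a **signature** (CpG list with signed ±1 or
real-valued weights plus an intercept). TSV with CpGs as rows is the
interchange format, matching the orientation of public series matrices;
writers emit 12 significant digits so read/write round trips preserve at
least 10.

Missing betas are never imputed. Each consumer declares its policy:
deconvolution drops missing CpGs per sample (not listwise), the
moderated t-test drops incompletely observed CpGs with a logged count,
and signature scores intersect the signature with the available CpGs
(floor of 3 for correlation scores, 1 for linear scores).

## Deconvolution

Per sample, marker betas are regressed on the reference columns plus an
intercept by a Huber M-estimator: weights `min(1, c·σ̂/|r|)` with
c = 1.345 (95% Gaussian efficiency), scale σ̂ re-estimated each iteration
as MAD/0.6745, iterated to a coefficient-change tolerance of 1e-6 or at
most 500 iterations. A perfect fit (σ̂ < 1e-10) short-circuits to the
OLS solution, which makes noiseless recovery exact to machine precision.
Negative coefficients are truncated to zero and the remainder
renormalized to sum to one; renormalization is a flag (default on)
because robust-deconvolution implementations differ on whether raw
truncated weights are reported. The intercept (default on) absorbs
global intensity shifts; it can be disabled for exact comparison against
constrained least-squares oracles. An all-zero coefficient vector falls
back to uniform fractions with a warning; a rank-deficient reference
raises an error naming the most collinear cell-type pair.

The hierarchical estimator multiplies the stage-1 parent fraction by the
stage-2 relative subtype split, so subtype fractions sum exactly to the
parent fraction by construction. Its exactness on synthetic data relies
on subtype-marker CpGs carrying no signal in other lineages (other cell
types sit at a fixed baseline there); on real data, contamination of
subtype markers by other lineages biases the relative split toward
uniformity — a limitation inherent to applying a two-column panel to
bulk tissue.

## Reference construction

The moderated t-test shrinks per-CpG pooled variances toward a
scaled-inverse-chi-square prior whose parameters (d₀, s₀²) are fit by
moment matching on log variances (digamma/trigamma inversion); the
statistic uses the shrunk variance with d + d₀ degrees of freedom,
capped at the pooled residual degrees of freedom across CpGs. With
`prior_df = 0` it reduces exactly to the ordinary pooled t-test, and its
t and p values agree with limma's `eBayes` to four significant figures
(cross-checked in the test suite via Rscript). FDR is Benjamini–
Hochberg.

The gap specificity score of a CpG is the signed distance from the most
discriminative cell type's mean (the one furthest from its nearest
neighbor) to that nearest other mean; for two groups its magnitude is
|Δβ|. Markers require FDR < 0.05 and |gap| ≥ 0.3 (defaults), ranked by
descending gap with ties broken by ascending p then CpG id, so selection
is invariant to sample and CpG order. Direction balancing (default on)
keeps equal numbers of hyper- and hypomethylated markers when both
directions exist; with only one direction present it degrades gracefully
to unbalanced selection. Reference values are arithmetic means of the
contributing sorted samples.

## Signature scores

Z-scoring is cohort-wise (each CpG to mean 0, sd 1 with ddof = 1 across
the samples at hand), so correlation scores are comparable within but
not across cohorts — re-scoring a merged dataset changes the values.
The signed score is the Pearson correlation of a sample's z-profile with
the ±1 weight vector over the intersected CpGs; under independence its
null distribution has mean 0 and sd ≈ 1/√(S−1) for S signature CpGs,
which the tests verify by Monte Carlo at S = 1765. Flipping all signs
negates every score exactly, and any strictly positive rescaling of a
profile leaves its score unchanged. Relative age acceleration residuals
come from OLS of predicted on chronological age; they are centered and
uncorrelated with chronological age by construction. No published
clock or signature coefficients ship with the package; the signature
file format carries user-supplied weights, and the synthetic generator
emits a ground-truth signature for testing.

## Synthetic cohorts

The generator emulates the statistical regime the pipeline faces, not
array chemistry. Defaults: 19 cell types × 50 marker CpGs plus ~4050
baseline CpGs (≈5000 total), marker levels 0.85/0.10 with alternating
direction per type, baseline uniform(0.2, 0.8) shared across types.
Fractions are Dirichlet with concentration 40 × plausible blood means
(neutrophils ≈ 45%, rare types ≤ 2.5%); age (uniform 18–90) and sex
(Bernoulli ½) act linearly on the log-concentrations — per decade for
age — so fractions stay on the simplex at every age. Default drifts:
naive T/B compartments shrink, memory compartments and erythroid
precursors grow with age. The latent inflammation variable is
standardized age plus N(0, 0.5²) noise; the signature shifts 100
randomly chosen non-marker CpGs by ±0.02 per latent unit (clamped to
[0.01, 0.99]). Measurement noise is Beta(mean·λ, (1−mean)·λ) per cell —
respecting the [0, 1] support and the heteroscedasticity of array betas
— with λ = 200 for cohorts (per-CpG sd ≈ 0.03 at β = 0.5) and λ = 500
for sorted samples generated from a panel's own profiles. Everything is
deterministic given the config seed.

What the generator does not emulate: probe-type chemistry, batch and
chip effects, genetic variation at probes, cross-platform probe overlap,
or correlated noise across CpGs. Passing tests therefore demonstrate the
correctness and calibration of the algorithms under the stated
generative assumptions, not performance on any real cohort.

## Spike-in experiment

Nine bins of true rare-cell fraction (0%, 0–0.1%, 0.1–0.5%, 0.5–1%,
1–2%, 2–4%, 4–6%, 6–8%, 8–10%), 1000 mixtures per bin, each built by
uniform sampling within the (half-open) bin, rescaling a sampled base
fraction row by (1 − f), and averaging one randomly chosen sorted
profile per cell type. Base fractions default to Dirichlet draws over
the six common immune types; any fraction matrix can be substituted.
The 0% bin's correlation is undefined (zero-variance truth) and is
reported as missing, not zero.

Sorted pools for the benchmark get beta noise at λ = 100 — noisier than
within-panel sorted samples — because spike material in practice comes
from independent datasets whose profiles differ from the reference more
than the reference's own constituents. With rare-type pools at purity
0.8, this reproduces the characteristic pattern of rare-cell
deconvolution: estimates truncated at zero inflate the mean where the
true fraction is scarce (positive pooled bias below 1%), the inflation
fades as the true fraction grows (turning into a mild purity-driven
underestimate near 10%), and per-bin correlation stays positive and
rises with the bin midpoint — ordering across samples is recovered even
where the level is biased. Contamination alone cannot produce the
inflation (it scales estimates by the purity); the zero-truncation of
noisy estimates is the mechanism.

## Association and meta-analysis

Fractions are standardized per cohort (unit variance, centered) before
OLS, so effects are per SD of fraction; numeric covariates are
standardized, categorical ones indicator-coded; complete cases only,
with logged exclusion counts. Constant fractions yield missing estimates
(warned), detected by value-uniqueness rather than a floating-point
variance test. A Bonferroni significance flag over the panel size is
emitted alongside raw p-values, never modified p-values. The weighted
fraction-trend estimator residualizes a per-donor fraction on covariates
(OLS), then regresses the residuals on age by WLS with per-donor cell
counts as weights, after excluding donors below a count floor
(default 30).

Meta-analysis uses inverse-variance weights; τ² is the closed-form
DerSimonian–Laird moment estimator (exactly testable by hand; the
common R default for the same task is REML, which differs numerically —
the test suite cross-checks against `metafor`'s DL implementation).
I² = max(0, (Q − (k−1))/Q) × 100, zero when k = 1 or Q = 0. Effect
p-values are normal-based; the heterogeneity p-value is χ²(k−1).

## Problem sizes and numerical choices

Simulation-backed checks use desk-scale sizes chosen to keep the full
suite and the acceptance script to a couple of minutes each: 200
noiseless mixtures for exactness (machine-precision recovery), 5050
CpGs / 18 samples for marker selection, 1000 Monte-Carlo draws for the
score null law, 9000 mixtures per spike-in regime, 300 meta-analysis
replicates for CI coverage, 1000 null cohorts for type-I error. Beta
means are clamped to [1e-6, 1−1e-6] before noise so the Beta
distribution is always well-defined; fraction row sums are enforced to
1e-8; IRLS convergence is 1e-6 on coefficients. Ties in marker ranking
break deterministically (gap, then p, then CpG id).

## Known limitations

- The two-group reference builder does not generalize marker selection
  to >2 cell types (the gap score itself does).
- Correlation-based scores are cohort-relative; absolute values are not
  comparable across datasets.
- The hierarchical subtype estimator inherits the bulk-contamination
  bias described above.
- No probe-level QC, normalization, or imputation: inputs are assumed
  preprocessed.
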