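# Methods

## The problem

Bulk brain expression profiles are mixtures over cell types, and any
condition that shifts the mixture — neuronal loss with astrocytosis and
microglial proliferation in neurodegeneration being the canonical case —
shifts measured expression without any per-cell regulatory change.
Chromosome X is a special case: X-linked expression is elevated in brain
(X up-regulation), and if that elevation is concentrated in neurons, a
loss of neurons appears as a *spatially coherent* depression of most of
chromosome X.  This package implements the analysis that detects such
chromosome-wide spatial patterns, associates them with cell-type
abundance proxies, and quantifies per-sample X:Autosome dosage — plus a
synthetic-cohort generator that makes the whole chain testable by
parameter recovery.

## Pattern extraction model

For one chromosome, let `Y` be the probes × samples matrix of log2
expression with probes in genomic order (rank-spaced: the wavelet axis
counts adjacent probes, not base pairs).  Each sample's signal is
extended by symmetric reflection to the least power of two and decomposed
to full depth in the orthonormal Haar basis; the transform is decimated
and energy-preserving, so a shift over a run of `L` adjacent probes
concentrates into few coefficients with amplitude ~`√L`, while probe-wise
noise stays flat across scales.  Writing `W` for the coefficient × sample
matrix, coefficients are centered across samples (the analysis describes
deviations between subjects, and an overall intercept would otherwise
dominate the first component) and factorized by SVD:

    W − W̄ = U S Vᵀ

* spatial pattern: `u₁` (unit norm, coefficient space),
* case loadings: `σ₁ v₁` (one scalar per subject, expression units),
* variance explained: `σ₁² / Σσᵢ²`.

Coefficients of `u₁` attributable to noise are removed by hard
thresholding before inverting back to a per-probe differential-expression
profile.  The default rule is the universal threshold
`σ̂ √(2 ln N)` with `σ̂ = MAD(finest-level details)/0.6745` and `N` the
coefficient count; `σ̂ = 0` (an already-sparse pattern) means threshold 0.
This is a deliberately standard, conservative stand-in for the original
tool's unpublished noise-inference rule; its conservatism matters (see
Limitations).  The SVD sign is fixed by requiring case loadings to
correlate positively with per-sample mean expression of the slice, so
"low loading = low chromosomal expression" is stable across runs.

Degenerate inputs: fewer than 2 probes or samples, non-finite values, and
all-identical samples (no between-sample variance) are rejected
explicitly rather than returning an arbitrary component.

## Normalization and ratios

Intensities are normalized per sample by the median over present-call
probes, then log2-transformed; the present-call median is thereby 1,
making samples comparable across arrays.  The X:Autosome ratio is the
mean *linear* intensity over X probes divided by the mean over autosomal
(chr 1–22) probes — log-scale means would be geometric means and would
not reproduce the ≈1 null under median normalization.  Y probes are
excluded from the denominator so the ratio is comparable between sexes.
Group comparisons are two-tailed pooled-variance Student t-tests.

## Reporter genes and association

Cell-type reporters are autosomal genes with strictly >20-fold enrichment
for one cell type in a reference table; chromosome X genes are excluded a
priori so the proxy cannot trivially correlate with an X pattern.  The
per-sample reporter summary is the first SVD component of the centered
log2 reporter-probe matrix (more robust than a plain average; the average
only orients the sign).  Association uses two-tailed Pearson correlation;
whether the astrocytic pattern adds information beyond the neuronal one
is a forward partial-F test: fit `y ~ x₁` and `y ~ x₁ + x₂` and refer
`F = (RSS₁ − RSS₂) / (RSS₂ / (n − 3))` to `F(1, n−3)` at α = 0.05.  If
the base model already fits to numerical precision there is nothing left
to explain and the added predictor is reported non-significant (F = 0);
if only the extended model fits exactly, it is reported significant.

## Synthetic cohorts

The generator is deliberately *mechanism-minimal*: a sample is a
fraction-weighted mixture of cell-type profiles (neuron, astrocyte,
microglia) with multiplicative log-normal noise,

    intensity[g,i] = (Σ_c f_ic · p_cg) · 2^ε,   ε ~ N(0, noise_sd_log2²),

and the cell-type profiles differ **only** through the two modelled
mechanisms: neurons multiply non-escape X probes by `x_factor_neuron`,
and reporter genes are suppressed (divided by the fold) in the cell types
they do not mark — a marker is expressed at its ordinary level in its own
cell type and near-silent elsewhere.  The per-probe base intensity is
drawn once, log2 ~ N(6, 1), identically for X and autosomal probes and
shared across cell types, so the null X:Autosome ratio is exactly 1 and
every downstream deviation is attributable to a modelled mechanism.

Key parameters (defaults):

| parameter          | default | meaning                                              |
|--------------------|---------|------------------------------------------------------|
| `x_factor_neuron`  | 1.3     | neuronal X up-regulation (dimensionless); gives a pure-neuron ratio of ≈1.3·0.85 + 0.15 ≈ 1.26 and a clear cohort separation without saturating. The field reports brain X up-regulation qualitatively, not as a number; 1.3 is a tunable stand-in. |
| `escape_fraction`  | 0.15    | share of X probes in the contiguous low-coordinate (telomeric Xp) escape zone, exempt from up-regulation; >15% of human X genes escape inactivation, mostly on Xp. |
| `reporter_fold`    | 25      | own-vs-other cell-type enrichment of reporter genes (must exceed 20, the selection threshold). |
| `noise_sd_log2`    | 0.25    | multiplicative measurement noise, log2 scale — typical microarray replicate scatter. |
| group compositions | control (0.60, 0.25, 0.15), disease (0.30, 0.40, 0.30) | mean (neuron, astrocyte, microglia) fractions; disease halves the neuronal fraction with compensatory astrocytosis/microgliosis. |
| `concentration`    | 40      | Dirichlet concentration; within-group fraction sd ≈ 0.08, small against the 0.3 between-group difference. |

Fractions are Dirichlet on the simplex; the `independent_astrocyte` mode
draws neuron and astrocyte fractions as independent Betas (microglia
takes the remainder, rejection-sampled onto the simplex).  That mode is
the null scenario for the stepwise test: when astrocyte abundance carries
no information about neuronal loss, the astrocytic predictor should be
declared non-significant at the test's type-I rate.  Note that in the
*default* design astrocytosis is coupled to neuron loss — there the
astrocytic pattern legitimately correlates with the X loadings and may
add information; that is a property of the design, not a failure of the
test.  Sex is metadata only (no simulated sex effect); ages are drawn
around 75 y and carry no expression effect.

Problem sizes: analyses and tests use 6000 autosomal + 600 X probes with
12 control + 12 disease samples, ten seeded replicates; ratio-null checks
use 2000 + 2000 probes.  These sizes put Monte-Carlo error comfortably
below the assertion tolerances while keeping any run in seconds.

## What the generator does and does not emulate

It emulates: mixture structure of bulk tissue, neuron-specific X
up-regulation with a spatially contiguous escape zone, strongly enriched
cell-type markers, multiplicative noise, detection calls, and pure-cell
cohorts (laser-dissected neurons, cultured microglia).

It does **not** emulate: cell-type transcriptome divergence beyond the
modelled mechanisms (real neurons and glia differ across thousands of
non-marker genes), probe-sequence or platform artifacts, batch effects,
A/B-chip structure, sex-linked expression differences, or any disease
effect other than composition change.  The omission of broad cell-type
divergence is the important one: such divergence adds
composition-correlated fine-scale structure to the extracted pattern,
which inflates the noise estimate of the universal threshold and
degrades escape-zone resolution (measured here: adding an independent
per-cell-type log2 deviation of sd 0.25 roughly halves the rate at which
the escape zone is resolved).  Passing recovery tests therefore
demonstrate correctness of the machinery under the modelled mechanisms,
not that escape-zone resolution survives in real tissue.

## Numerical choices

* Padding: symmetric (mirror) reflection on the right to the next power
  of two, recorded and stripped on inversion; reflection avoids spurious
  boundary jumps that zero-padding would create.
* Probe ordering: ascending genomic start, ties broken lexicographically
  by probe id — a fixed, reproducible convention.
* Detection: synthetic detection calls default to all-present; an
  optional per-sample quantile floor marks the dimmest probes absent.
  Whole-tissue analyses default to no present-filtering of probes;
  pure-cell cohorts use the all-samples rule.
* Thresholding is strict (`|c| < t` is zeroed, `|c| = t` survives); the
  denoised pattern is *not* re-normalized, so profile amplitudes remain
  comparable to the unthresholded inversion.
* Collinearity guard: the partial-F test rejects predictor pairs with
  |r| = 1 to machine precision; Pearson p-values are clipped into (0, 1].

## Limitations

* The universal threshold is conservative: when the coherent pattern is
  nearly chromosome-wide, mid-scale coefficients carrying the escape-zone
  boundary sit close to the threshold, and for occasional replicates only
  the chromosome-average coefficient survives, flattening the profile.
  A recalibrated or level-dependent rule would resolve boundaries more
  reliably; it is intentionally not the default to keep the stated rule.
* First component only: conditions with two comparable spatial processes
  on one chromosome would need further components.
* Gene↔probe matching for reporters is exact string equality on symbols;
  aliasing is out of scope.
* The X:Autosome ratio's equal-base-law null holds for reporter-free
  probe sets; marker suppression removes autosomal mass in non-own cell
  types, so cohorts with a large marker share show a small upward ratio
  bias (~2% at the default 120/6000 share).
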