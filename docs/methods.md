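# Methods

## Model

Each trait `j` of each subject is a smooth random function on a closed
interval, observed at a small, subject-specific set of times with
additive iid Gaussian measurement error:

    X̃_ij(t) = μ_j(t) + Σ_k ξ_ik[j] φ_k[j](t) + ε_ijt .

The component scores ξ are uncorrelated within a trait with variances
λ_1 ≥ λ_2 ≥ …, but may be correlated *across* traits; that cross-trait
dependence is what the joint analysis exploits.  All downstream
structure (joint PCA, HDR clusters, outcome comparison) operates on the
estimated scores, so estimation quality of the per-trait decomposition
governs everything else.

## Estimation pipeline

**Mean.** Local linear smoothing of the pooled (time, value) scatter
with a Gaussian kernel.  The scatter is pre-binned to the nearest node
of the output grid; each occupied bin contributes its within-bin mean
time (not the node) as the design point, which preserves the local
linear property of reproducing constant and linear signals exactly.

**Covariance surface.** Raw covariances of mean-centered observations
at pairs of distinct times within a subject are smoothed by a local
linear surface smoother.  Same-time products are excluded: their
expectation carries the measurement-error variance.  Above 5000 raw
pairs the scatter is binned to the tensor grid, where all kernel moment
sums factorize into per-axis matrix products and the cost becomes
independent of the pair count; below that, the exact scatter is used.
The smoothed surface is symmetrized.

**Bandwidths.** Generalized cross-validation over ten geometrically
spaced candidates between the largest design gap and half the domain.
The GCV residual sum includes the within-bin dispersion (a constant in
the bandwidth but not in the GCV denominator; omitting it makes the
criterion reward interpolating bin means).  For the surface, the GCV
minimizer is multiplied by 2.0: raw covariance pairs from one subject
share that subject's score realization, GCV treats them as independent
and systematically undersmooths, leaving spurious high-order
eigencomponents (top-two variance share ≈ 0.90 instead of ≈ 0.96 on
two-component synthetic data).  The fixed inflation is the usual
pragmatic correction for cross-validation under correlated errors; with
it the top-two share is ≈ 0.96, component-count selection at a 0.95
variance-explained threshold behaves as intended, and eigenvalue
attenuation stays under ten percent at n = 1000.

**Eigenpairs.** Trapezoid-weighted discretization of the covariance
operator (symmetrized as W^{1/2} G W^{1/2}); eigenvalues then estimate
the functional eigenvalues directly.  Non-positive and negligible
(≤ 1e-12 of the leading) eigenvalues are dropped.  Signs are fixed
deterministically: the quadrature integral of each eigenfunction is
made non-negative, falling back to a non-negative left-endpoint value
when the integral is within 1e-8 of zero.  Reproducible signs matter
because the archetype labels read the *direction* of each component.

**Measurement-error variance.**  Two estimators are provided.

* `projection` (default): pooled squared norm of each subject's
  residual vector projected orthogonally to the span of the leading K
  eigenfunctions evaluated at that subject's times, divided by the
  pooled degrees of freedom Σ(N_i − K).  Per-subject score fluctuations
  live in the projected-out span, so the estimator's sampling sd is
  about 0.008 at the synthetic design's scale; its bias is the small
  trajectory energy leaking through eigenfunction estimation error
  (measured ≈ +0.017–0.027 against a true 0.01 at n = 1000, shrinking
  with n).
* `difference`: the classical construction — local linear smooth of
  same-time squared residuals minus the surface diagonal, averaged over
  the central half of the domain and floored at zero.  The diagonal of
  the surface entering the subtraction comes from a rotated local fit,
  quadratic orthogonal to the diagonal, which keeps the ridge curvature
  a plain local linear smooth flattens.  Unbiased before flooring, but
  its per-fit sd is ≈ 0.2 at this sparsity (5–10 observations per
  subject): the diagonal and off-diagonal kernel weightings give each
  subject's trajectory-energy fluctuation slightly different weights
  and the mismatch dominates.  The zero floor then inflates the mean.
  Neither estimator pins the noise variance tightly at this design;
  the projection default is far better behaved and is what the scores
  use for shrinkage.

**Scores.** Best linear prediction given the subject's own observations,
with mean and eigenfunctions evaluated at subject times by linear
interpolation from the grid and a ridge of 1e-8·trace/N_i when the
noise variance is exactly zero.  In the dense noiseless limit the
scores agree with direct quadrature integration up to an O(1/G)
endpoint-weight effect.

## Joint features and archetypes

Score blocks are stacked across traits and reduced by PCA on the sample
covariance; each eigenvector's sign makes its largest-magnitude loading
positive.  Two conventions are supported:

* `standardize=True`: each score column is divided by √λ̂ first, so the
  PCA operates on the cross-component correlation structure.  This is
  the convention for the general data-analysis workflow (and the CLI
  `analyze` default).
* `standardize=False`: PCA on the raw scores.  This is the simulation
  study's convention — the synthetic outcome is built from the leading
  eigenvectors of the *unstandardized* score covariance (trace 15,
  leading eigenvalues 4.041 and 3.068), and the Monte-Carlo study uses
  it for consistency with that outcome model.  Measured at n = 1000,
  running the standardized variant against the unstandardized outcome
  roughly halves the frequency of resolving three or more clusters.

The HDR uses a product-Gaussian kernel density with per-coordinate
normal-reference bandwidths 1.06·sd·n^{-1/5}, evaluated leave-self-in
at the sample points; the density threshold is the empirical α-quantile
(lower order statistic) of those values, so the flagged fraction is at
most α by construction.  Quadrant labels compare |Z1|/√ρ1 with
|Z2|/√ρ2; exact ties break toward the Z1-dominant cluster and a zero
deciding coordinate defers to the sign of the other — measure-zero
events fixed deterministically for reproducibility.

## Outcome association

ANOVA, tie-corrected Kruskal–Wallis, and Tukey HSD (Tukey–Kramer for
unequal sizes; scipy's implementation) run on the four outlier
subgroups only; the "normal" group is excluded from testing but still
drawn in conditional-density summaries (Gaussian kernel, Silverman
bandwidth on the pooled outcomes).  Subgroups with fewer than two
members are excluded from the post-hoc family and from separation
counting (`min_size = 2`).  "Completely separated clusters" is the
number of connected components of the graph joining subgroup pairs
whose adjusted p is at or above the family-wise level; under this
reading every pair across two components differs significantly.  Note
the count is conservative under a global null: splitting off one
subgroup requires that *all* its pairwise comparisons reject, so the
frequency of seeing two or more separated clusters with a null outcome
sits well below the family-wise level (measured 0/30 repetitions at
n = 1000).

## Synthetic cohorts

The generator draws the six scores from the stated 6×6 covariance,
builds trajectories from the two Fourier basis functions, samples
N_ij ~ uniform{5..10} observation times iid Uniform(0,1) per trait,
adds noise with sd 0.1, and sets Y = 0.4·Z1 + 0.2·Z2 + N(0, 0.4²) with
Z the leading population joint components.  Everything derives from one
integer seed.  What it does *not* emulate about real growth data:
visit-schedule clustering of measurement times, monotone growth with
age-dependent variance, non-Gaussian score distributions, and
confounder structure.  Passing tests therefore certify the estimation
machinery under a correctly specified sparse functional model, not
robustness to those departures.

Default study conditions (n = 1000 subjects, α = 0.05, two components
per trait, family-wise 0.05 Tukey) follow the simulation design; the
Monte-Carlo driver defaults to 200 repetitions, a desk-scale choice
that resolves histogram fractions to about ±3 percentage points (the
full-scale study used 1000).

## Numerical choices and degenerate inputs

Grid: 51 equally spaced points by default.  Gaussian kernels
throughout (always-positive weights avoid singular local fits in
sparse windows); singular local systems raise with advice to enlarge
the bandwidth.  Constant samples have a zero covariance surface and
raise a degenerate-sample error.  Subjects must be observed on every
required trait (the joint step needs complete score vectors); subjects
failing this or lacking outcomes are dropped with logged counts.

## Known limitations

* The noise-variance estimators cannot pin σ² to better than a few
  times its true value at 5–10 observations per subject (details
  above); scores are mildly over-shrunk as a result.
* HDR outlier sets are O(n²) in the kernel evaluation — fine to a few
  tens of thousands of subjects, not beyond.
* The archetype name mapping (S1..S4 → Generally Large / Catch-up /
  Stunting / Faltering) is the growth-study reading of the quadrants
  and is configurable; for other domains the labels are just the four
  dominant-direction clusters.
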