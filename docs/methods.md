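# Methods

## Monitoring model

hiPCA casts gut-microbiome health prediction as multivariate statistical
process control. The "in-control" process is the healthy gut: a PCA model is
fitted to healthy samples only, and a new sample is judged by how far it
departs from the healthy covariance structure. This rests on two
assumptions: (i) healthy microbiomes share a reproducible low-rank
correlation structure among a core set of species, and (ii) disease
manifests as departure from that structure rather than as one fixed
signature (the Anna Karenina view — unhealthy microbiomes vary more, each in
its own way). Nothing about any particular disease is used at fit time, so
the same boundary applies to every phenotype.

Three charts monitor complementary subspaces. Hotelling's T² measures
in-model variation (abnormal scores along retained components); Q (squared
prediction error) measures off-model variation (correlation breakage); the
combined index φ = T²/τ² + Q/δ² merges both so one threshold, ζ², defines
the health boundary. φ is the user-facing health index; lower is healthier.
The decomposition φ = T²/τ² + Q/δ² holds exactly by construction and is
asserted in tests.

Control limits come from χ² theory: τ² = χ²α(d) is exact for Gaussian
scores; δ² and ζ² use the standard moment-matching (Box / Jackson–Mudholkar
style) approximations with possibly non-integer degrees of freedom, so the
continuous χ² quantile function is used throughout. Eigenvalues below
1e-12 (relative) are floored to zero before the θ₁, θ₂ sums so a numerically
rank-deficient residual spectrum cannot corrupt the limits. When θ₁ = 0
(no residual subspace) δ² and ζ² are undefined and the model is restricted
to T²-only monitoring, which `score()` reports as an explicit error for
φ-based rules.

Eigenvector signs are fixed by making the largest-magnitude loading of each
component positive; all indices are quadratic forms and therefore invariant
to this convention (property-tested). PCA decomposes the covariance of the
already z-scored matrix — equivalent to correlation PCA of the transformed
abundances.

## Preprocessing

Relative abundances (percent scale) pass through

    lt(x) = log2(2x + σ),  x ≤ 1;    lt(x) = √x,  x > 1,

which expands the low-abundance range where most species live while keeping
large abundances bounded; the two branches nearly meet at x = 1. σ defaults
to 1e-5 — below the smallest typical nonzero MetaPhlAn2 percentage — so
lt(0) = log2 σ is finite and well separated from observed values. Z-score
parameters (per-feature mean and sd, ddof = 1) are estimated on the healthy
training cohort and frozen; prediction never refits them, and repeated
scoring of the same table is bit-identical. Zero-variance features are
dropped from the panel with a logged record. Missing model features at
predict time are an error unless fill-missing is enabled, in which case the
feature is imputed as abundance 0 and pushed through the same transform.

Species panels come from one-sided two-sample Kolmogorov–Smirnov tests on
the raw abundances (the statistic is invariant under the monotone
transform): a species is health-scarce (H−) when its abundance is
stochastically larger in the unhealthy cohort, health-prevalent (H+) when
larger in the healthy cohort. The H− and H+ inclusion thresholds are
independent knobs to support threshold scans; modeling defaults to the H−
panel only, with H+ inclusion behind a flag. The exact/asymptotic P-value
switch is left to scipy's `ks_2samp` (asymptotic above ~100 samples per
group) and the mode used is recorded in the selection result.

## Contribution diagnosis (BHC)

The contribution of a direction ξ to a quadratic index Ind(x) = xᵀMx is the
index reduction achievable by moving the sample along ξ:
Ind(x) − min_f Ind(x − ξf) = xᵀMξ(ξᵀMξ)⁻¹ξᵀMx. Per-species contributions
use coordinate directions and are computed in closed form ((Mx)ᵢ²/Mᵢᵢ);
multi-species blocks use the pseudo-inverse with relative tolerance 1e-10,
and rank deficiency is logged rather than fatal. Single-direction
contributions are non-negative and never exceed the index itself; for
M = I they sum exactly to Ind(x), but for general M no such additivity holds
and none is asserted. Population-averaged spectra are arithmetic means over
a phenotype group.

High-contributor sets per disease take species in descending contribution
order until the accumulated share *strictly* exceeds the target ratio
(default 0.8); broad-spectrum species are the intersection of those sets
across diseases. Disease spectra are clustered agglomeratively with average
linkage on correlation distance by default — the choice is a package
decision, both the metric (euclidean available) and profile standardization
are exposed because the underlying analysis admits either.

## Contrastive pattern discovery

Healthy sub-patterns are directions with high healthy variance but low
unhealthy variance: the top eigenvectors of S_h − α·S_uh. α = 0 recovers
ordinary PCA of the healthy cohort (the two code paths share one
eigen-solver and agree bit-for-bit); larger α progressively suppresses
variance shared with the unhealthy background. The default grid is 0 plus
20 log-spaced values in [0.1, 1000]; automatic selection fits a GMM per α
and keeps the α with the best mean silhouette, breaking ties toward the
smallest α. Projections onto the top 2 contrastive components (the count is
configurable; the underlying analysis does not fix it) are clustered by
full-covariance Gaussian mixtures with 10 restarts at a fixed, recorded
seed; AIC (default) or BIC traces are recorded over the scanned component
range and the minimum selects the pattern count.

A caveat measured during development: argmin-AIC over full-covariance GMMs
overselects by one component in roughly 10–15% of datasets even for ideal,
well-separated Gaussian clusters (the spurious component splits one cluster
into two overlapping halves for a few AIC units). This is a known property
of AIC for mixtures, is insensitive to sample size, separation, and the
scanned range, and is why the BIC trace is always recorded alongside. When
overselection happens the partition is still essentially correct (ARI
≈ 0.9 or better against the planted patterns).

## Synthetic cohorts

The generator works backwards through the preprocessing chain so that every
stage of the pipeline is testable without downloads. Healthy samples are a
Gaussian factor model in the transformed-standardized space: d_true latent
factors (default 8) mapped through random orthonormal loadings, scaled so
every feature has unit variance and the factors carry a 0.92 share of total
variance — strong low-rank correlation, so the default explained-variance
target 0.9 retains approximately the true rank. Features map to percent
abundances through the inverse transform with per-species baselines drawn
log-uniformly over 1e-3..10 percent and transformed-scale spreads in
[0.5, 1.5], matching the magnitude range of MetaPhlAn2 species profiles.
Sparsity is imposed by zeroing abundances below a population-level cutoff
frozen at the target zero fraction (default 0.30), so independently drawn
cohorts are identically distributed. Unhealthy samples add a planted shift
(default 6, in transformed-standardized units) along known fault species
before back-mapping; multi-pattern healthy cohorts place pattern means
(regular-polygon layout, separation in units of the unit within-pattern
spread) in a 2-D latent subspace that carries only baseline variance in the
paired background cohort, so plain PCA of the target is dominated by the
shared factors and contrastive learning is required to resolve the patterns.

What the generator does *not* emulate: taxonomic or phylogenetic structure,
compositional closure (rows are not renormalized to 100%), sequencing-depth
noise, and the heavy-tailed, non-Gaussian residual variation of real
profiles. Passing tests therefore demonstrate that the machinery behaves as
its theory predicts under its own assumptions — Gaussian factor structure,
known faults — not that real cohorts meet those assumptions.

Sparsification deliberately breaks the Gaussian assumption (zeroed cells
become a point mass at lt(0) after transform), which inflates tail
exceedance beyond the χ² nominal rates and attenuates planted shifts
relative to their nominal standardized size. Calibration and planted-fault
recovery are therefore measured on dense cohorts (zero fraction 0), where
the transform chain is exactly invertible and "a shift of k normalized
units" means exactly that; sparse cohorts exercise the screening,
evaluation, and end-to-end CLI paths.

## Evaluation conventions

Unhealthy is the positive class. η is the true-positive (detection) rate;
balanced accuracy is the mean of the true-positive and true-negative rates.
The weighted index PI = w·υ + (1−w)·η is implemented with υ as the
true-negative rate by default — so PI at w = 0.5 *is* balanced accuracy,
consistent with how the trade-off is used — with a strict mode using the
false-positive rate for completeness; maximizing the FP reading is
incoherent, which is why it is not the default. Threshold tuning refits the
model per explained-variance target, recomputes limits per confidence, and
returns the PI-argmax cell along with the full grid so the trade-off surface
is inspectable.

Shannon diversity uses the natural log over renormalized positive
abundances and richness counts strictly positive entries (standard ecology
conventions; the base is a convention, not a result). Spearman correlation
uses mid-ranks for ties with two-sided P-values; covariate outlier filtering
is caller-side, with a Tukey IQR-fence helper (k = 1.5) provided.

## Problem sizes and determinism

Desk-scale defaults are used throughout: D = 120 species, rank 8, 2000
healthy / 1000 unhealthy samples. Statistical checks use 20,000 fresh null
samples for calibration and 10–20 seeded replicates for recovery rates;
`scripts/acceptance.py` derives every stream from its `--seed` and completes
in well under a minute on one CPU. All fitted artifacts serialize to
versioned JSON with shortest-round-trip floats, so write → read reproduces
scores bit-exactly.

## Known limitations

- The χ² limits for Q and φ are approximations; their empirical exceedance
  is within ±0.02 of nominal under the Gaussian model but degrades with
  sparsity-induced non-Gaussianity (by design of the approximation, not the
  implementation).
- Linear PCA only: nonlinear healthy manifolds are out of scope.
- BHC attributes index reduction, not causality; strongly correlated
  species share contribution, and a fault on one species can surface its
  correlated partners in high-contributor sets.
- AIC pattern-count selection overselects occasionally (see above); treat
  the selected k as a starting point and consult both traces.
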