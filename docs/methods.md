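# Methods

This note records the models, defaults and design choices behind
`slidesample`, and what the synthetic experiments do and do not show.

## Geometry and units

Tiles are square patches of `patch_size_px` = 500 pixels at
`microns_per_px` = 0.5 (20X), i.e. 250 µm on a side.  Profiles are reported
in cells per 100-µm square, so the per-tile divisor is
(500 · 0.5 / 100)² = 6.25; densities are therefore resolution-independent
and raw counts are recoverable through the area factor.  Tiling is 0-based
and row-major; tile (r, c) covers the half-open pixel box
[rP, (r+1)P) × [cP, (c+1)P), and partial tiles at the right/bottom edges are
dropped.

## Segmentation and artifact handling

Tissue is separated from glass by local-entropy thresholding: entropy of
the intensity histogram in a 15-px window, thresholded by Otsu's criterion
on the entropy image (no fixed threshold is defensible across scanners, and
Otsu adapts to the bimodal tissue/glass entropy distribution), followed by
a morphological opening (radius 2 px) to drop specks.  A tile is foreground
iff at least `foreground_overlap_threshold` = 0.5 of its pixels are in the
mask; the threshold is exposed because "overlaps" is genuinely a modeling
choice, and the foreground count n_F is non-increasing in it.

Gray artifacts (coverslip edges, scanner smears) are foreground tiles that
are nearly unsaturated — mean per-pixel channel spread below 20 intensity
units — at mid-gray brightness (mean in [60, 200]).  White background fails
the brightness band; stained tissue fails the saturation test.  The
non-artifact fraction γ is estimated by uniformly probing n_probe
foreground tiles, giving an unbiased binomial estimator.  The *artifact*
flag refines *foreground*: n_F counts all tissue tiles (so γ·n_F is the
usable count used by the sample-grid formula), while both sampling policies
draw only from usable tiles.  In synthetic mode artifact status comes from
the generator's manifest; the pixel detector is unit-tested on constructed
patches.

## Sampling

RS draws uniformly without replacement from the usable tiles.  SRS
partitions the tile grid into g × g blocks anchored at the origin (no
random phase — the estimator is already unbiased per block, and a fixed
anchor keeps runs comparable), draws one tile uniformly per block, and
discards draws that land outside the usable set without re-drawing.  The
block side is g = ⌊√(γ n_F / n_nom)⌋ clamped to ≥ 1: a slide with γn_F
usable tiles cut into g²-tile blocks yields about γn_F/g² ≈ n_nom draws,
and the reference geometry (γ = 1, n_F = 900, n_nom = 100) gives the 3 × 3
blocks of the motivating design.  At g = 1 SRS enumerates every usable tile
in row-major order and is bit-identical to exhaustive tiling.

Policy comparisons use a matched-size protocol: SRS batch runs go first and
each RS batch reuses, slide by slide, the sample size the corresponding SRS
batch realized, so policies are compared at identical cost.  The RBD
denominator ("global average") is the pooled profile mean over all slides
and both batch runs of the same (policy, n_nom) configuration — applied
identically to both policies so the ratios are comparable.
`compare_policies(n_repeats=k)` repeats the whole two-batch protocol k
times with independent seeds and averages the RBD table; this reduces the
Monte-Carlo error of the comparison without changing its expectation, and
the end-to-end checks use k = 3 so that the twelve SRS-vs-RS orderings are
assessed well above the single-pair noise floor.

## The identifier stand-in

Real deployments plug a trained detector/classifier in through the
`CellIdentifier` contract (any callable `(cell_map, row, col) → CellMap`,
deterministic given its own seed).  The shipped `OracleIdentifier` perturbs
ground truth with a per-cell miss probability (default 0.35, i.e. 0.65
detection accuracy) and a per-cell label draw from a confusion matrix
(default: 0.76 on the diagonal, the remainder spread evenly), matching the
hand-mark evaluation averages of the identifier it stands in for.  Its
per-tile random stream is derived from (seed, row, col), so output is
independent of tile visiting order — as a trained network's would be.
Detection scoring matches predictions to truth greedily by increasing
distance with a one-to-one constraint inside a 12-px radius (≈ one nucleus
radius at 20X); exhaustive optimal matching bounds the greedy matcher in
tests.  Normal and malignant epithelial labels are merged before scoring
because the identifier does not separate them.

## Synthetic cohort model

Per slide, the expected density of type j at tile t is log-Gaussian:

    log λ_j(t) = log m_j + δ_j − (σ_sp² + σ_sl²)/2 + σ_sp G_j(t) + σ_sl v_j

- m_j: cohort mean densities, defaults (21.3, 5.52, 5.64, 2.43) cells per
  100-µm square for (epithelial, inflammatory, fibroblast, other).
- G: unit-variance Gaussian fields built by mixing white noise across types
  with the Cholesky factor of the target correlation matrix, smoothing each
  plane with a periodic Gaussian kernel of scale `correlation_length`
  tiles, and renormalising to unit variance (the kernel's L2 norm is
  computed exactly on the grid).  Identical per-type smoothing leaves the
  pointwise cross-type correlation untouched.  The default target matrix
  carries the observed sign pattern (epithelial vs fibroblast/other
  negative, fibroblast–other positive); an indefinite user target is
  repaired to the nearest unit-diagonal PSD matrix and rejected if the
  repair would flip a sign.
- v: a slide-level random effect with the same cross-type correlation,
  giving between-slide profile heterogeneity.
- δ_j: clinical log-shifts (below).  The −σ²/2 terms make
  E[λ_j] = m_j·e^{δ_j} exact, which is why cohort means recover their
  targets without calibration runs.

The log link (rather than a softplus-style squashing) was chosen because
the mean correction is closed-form and clinical effects become exact
multiplicative shifts; its cost is mild right-skew in slide profiles, which
the Welch t-test tolerates at the cohort sizes used.  Tile counts are
Poisson(λ · 6.25) — the canonical count model, with variance testable
against the mean — and nucleus coordinates are uniform in the tile,
materialized lazily from a per-tile stream so cohorts store count arrays,
not millions of points.  `SyntheticSlide.true_profile()` computes the
exhaustive perfect-identifier profile directly from the counts; its
equivalence with the materialized pipeline is unit-tested.

Foreground geometry is a union of random ellipses grown past the target
tile count, then peeled/dilated tile-by-tile to hit it exactly — one or a
few connected blobs with ragged edges, like a tissue section.  Artifact
tiles are flagged independently with probability `artifact_fraction`
(1 − γ).

Defaults and rationale:

| parameter | default | why |
| --- | --- | --- |
| n_slides | 142 | the emulated cohort size |
| grid_shape / target_foreground_tiles | (36, 36) / 900 | ~900 tissue tiles per slide |
| correlation_length | 3 tiles | tumor/stroma regions span several 250-µm tiles (~750 µm); no measured value exists for this scale, so it is a free, exposed parameter |
| spatial_log_sd σ_sp | 0.5 | tile-level CV ≈ 0.53 — strong within-slide heterogeneity, which makes sampling design matter; yields batch differences of the observed order |
| slide_log_sd σ_sl | 0.35 | between-slide CV ≈ 0.36, modest relative to real cohorts (which also vary in stain and site) |
| artifact_fraction | 0.0 | the clean-slide condition, under which the reference geometry reproduces g = 3 exactly; artifact paths are exercised via config and dedicated tests |

Clinical variables are binary with exact allocation: round(n·fraction)
slides drawn at random get the second level, so design group sizes (e.g.
120/21) are met exactly.  A variable with target group means (m_j0, m_j1)
shifts member slides' log-densities by log(m_jg/m_j); multiple effects add
on the log scale.  An empty effect list gives a valid null cohort.

## Association battery

Binary variables: two-sided two-sample t-tests of profile means, Welch by
default (group variances differ when means do, under the multiplicative
model) with a pooled-variance option.  Continuous variables: Pearson
correlation.  Variables with more than 30% missing values (configurable) or
a single observed level are dropped; missingness is handled listwise per
test; groups need ≥ 2 slides.  All executed variable × type tests form one
Benjamini–Hochberg family (step-up, via the standard statsmodels routine;
an independent brute-force step-up oracle checks every threshold in the
property tests).  The report carries group sizes, means, the statistic, raw
and BH-adjusted p-values, and the significance flag.

## What the synthetic experiments show — and what they do not

Passing cohort-scale checks demonstrates internal statistical correctness:
unbiasedness of both policies for the exhaustive profile, the variance
advantage of SRS under positive spatial autocorrelation, RBD shrinking with
sample size, FDR control on null cohorts, and recovery of a planted
group-mean effect at realistic sizes (power ≈ 0.85 for the fibroblast
contrast at n = 120/21).  The generator does not emulate stain variation
across sites, nucleus shapes or pixel textures, detector errors that
correlate with tissue content, artifact spatial clustering, or non-Poisson
overdispersion within tiles — so these results validate the sampling and
inference machinery, not any claim about a particular scanner or cohort.
Problem sizes in the test suite (e.g. 142 × 900-tile cohorts for the batch
comparison, 200–500 replicates for power/FDR, reduced grids where only
label structure matters) were chosen as the smallest at which the targeted
effects are comfortably resolved above Monte-Carlo noise.

## Numerical notes

- All randomness flows through `numpy.random.default_rng` with explicit
  seed lists; identical (config, seed) inputs give bit-identical cohorts,
  samples and profiles.
- Smoothing uses periodic ("wrap") boundaries so the field is stationary
  and the variance renormalisation is exact; the toroidal seam is invisible
  at the default correlation length.
- Degenerate inputs fail loudly: empty tile samples raise
  `EmptySampleError` (slides are excluded from batch statistics and logged,
  never zero-filled, since a mean over zero tiles is undefined); zero-
  variance groups, empty truth sets and malformed confusion matrices raise
  `ValueError`.
- `mean_accuracy` rounds to two decimals, the precision at which per-slide
  accuracies are tabulated.
- Greedy detection matching is order-stable (ties broken by candidate
  order after a stable distance sort), making evaluation deterministic.
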