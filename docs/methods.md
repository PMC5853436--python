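# Methods

`rootlda` analyses cohorts of 2-D seedling root systems: it turns each
plant's curve geometry into quantitative variables, and asks — with linear
discriminant analysis and resampling inference — whether root-system
architecture differs between groups of plants (here: nitrogen-uptake-
efficiency class and nitrate level in the growth medium). This note
records the models, conventions and numerical choices, and what the
synthetic cohorts do and do not establish.

## Coordinate and group conventions

Geometry uses the image convention: x horizontal, y increasing downward,
the seed at the origin, so depth is positive. Angles are measured in
degrees from the downward vertical. Groups are coded 0 = low NUpE / low
nitrate, 1 = low NUpE / high nitrate, 2 = high NUpE / low nitrate,
3 = high NUpE / high nitrate (figure colours: black, magenta, green,
blue).

## Synthetic cohorts

The generator is a gravitropic correlated random walk, not a botanical
growth model; its only contract is to produce cohorts whose trait
distributions carry planted group differences of known size, so the
downstream statistics can be exercised and calibrated.

Each seminal root starts at the seed with a signed emergence angle
~ N(mean, sd), grows in 1 mm segments, and after each segment relaxes its
heading toward vertical, `theta <- (1 - g) theta + noise`, with
gravitropism weight `g` (default 0.05) and heading noise N(0, 4°). The
seminal count is Poisson (mean 5) truncated to at least 1; seminal length
is log-normal (median 120 mm, log-sd 0.25). Laterals emerge as a Poisson
process (default 0.12 mm⁻¹) along each seminal beyond a 10 mm basal
offset, branch at ±N(60°, 12°) relative to the parent's local heading,
and grow by the same rule with log-normal lengths (median 8 mm, log-sd
0.45).

The demo cohort has 9 wheat lines (4 low-NUpE, 5 high-NUpE) × 2 nitrate
levels with one absent cell (line W199 at high nitrate), i.e. 17 cells,
and 17 plants per cell (289 plants) by default. The planted effect
profile makes the NUpE contrast dominant — low-NUpE groups have seminal
lengths and lateral densities about one within-group sd below the
high-NUpE groups — and gives the nitrate contrast a larger shift within
the low-NUpE groups than within the high-NUpE groups (log-mean length
shifts −0.25/−0.37 vs 0/−0.04, densities 0.085/0.10 vs 0.12/0.125).
These levels were fixed once as a realistic "clearly detectable but not
trivial" design; there is no quantitative distributional information
about the original plants to calibrate against, only the qualitative
ordering of effects.

Randomness: each plant draws from its own counter-based substream
(`SeedSequence(entropy=rng_seed, spawn_key=(plant_index,))`), so cohorts
are bit-reproducible and per-plant generation order is irrelevant.

What the generator does *not* emulate: image segmentation error, spline
smoothing artefacts, root crossings/occlusion, pouch-edge effects,
line-specific (as opposed to group-specific) architecture, and any
time-course. Passing tests therefore show that the statistical machinery
recovers planted multivariate effects of ~1 sd at these sample sizes —
not that real wheat lines differ.

## Traits

Eleven per-plant traits: total root length (sum of polyline arc lengths);
average seminal and lateral lengths; seminal and lateral counts; convex
hull area of all curve points (0 when degenerate); maximum width (x
extent); maximum depth (below the seed, since seeds sit at the top);
width/depth ratio (0 when depth is 0); and average seminal emergence and
tip angles. The angle of a seminal is the unsigned angle between the
downward vertical and the chord over its proximal (emergence) or distal
(tip) 10% of arc length; 10% is a stability choice (exposed as
`angle_window`) since the window used by common root-imaging tools is not
published, and angles are averaged over seminal roots only. With the
five MDS coordinates this gives 16 variables per plant.
Standardization scales every column to mean 0 and sample (N−1) variance
1; zero-variance columns are an error naming the column.

## Root-system distance and shape coordinates

Both systems are re-anchored at their seed; every curve is resampled to
m = 50 points equally spaced in arc length. The cost between two curves
is the root mean square of the pointwise Euclidean gaps. Seminal sets
are matched by minimum-total-cost assignment (Hungarian algorithm on a
square-padded cost matrix); an unmatched curve pays its RMS distance to
the degenerate curve at the origin, so root-count differences contribute
and the assignment itself chooses which curves go unmatched. Lateral
sets are matched the same way, independently of their parents, and the
distance is seminal cost + w·lateral cost (default w = 1). The measure
is symmetric, zero on identical systems and translation-invariant by
construction, but it is *not* guaranteed to satisfy the triangle
inequality (assignment plus penalty can violate it), and no normalization
by root count is applied — size information is retained deliberately so
the shape coordinates may correlate with plant size, which they do
(Geom1 tracks total length on default cohorts). Knobs: m, w.

Classical (Torgerson) MDS embeds the distances: B = −½ J D∘D J,
eigendecompose, coordinates = top-k eigenvectors × √eigenvalue, k = 5
(Geom1–Geom5). Negative eigenvalues from the non-Euclidean distance are
dropped and their total magnitude recorded. Sign convention: each
coordinate is flipped so its largest-magnitude entry is positive
(deterministic across platforms); the same rule orients PCA axes.

## Discriminant analysis

For groups g and variables p, H and E are the between- and within-group
scatter matrices (T = H + E). The discriminants solve the eigenproblem
of E⁻¹H by whitening with the Cholesky factor of E; r = min(p, g−1)
eigenvectors are kept in descending eigenvalue order. Loadings are
scaled so aᵀS_w a = 1 with S_w = E/(N−g) — scores then have unit pooled
within-class variance, which makes loading magnitudes comparable and is
the convention assumed throughout. Scores are centred at the grand mean.
Signs: LD1 is oriented by a reference contrast when one is supplied (the
"low" side of the NUpE class gets the lower mean score); discriminants
without a contrast flip so their largest-magnitude loading is positive.

Mahalanobis distances between line×nitrate cells use, by default, the
within-cell covariance pooled over *all* cells (N−G degrees of freedom):
with 16 variables and ~34 plants in a pair of cells, pair-pooling is
barely full-rank and unstable. Pair pooling remains available. Heat
maps are emitted in two orderings: each line's two nitrate cells adjacent
(grouped low- then high-NUpE), or nitrate blocks within NUpE blocks.

Mean confidence regions per group are normal-theory ellipses
{μ̂ + u : uᵀ(Σ̂_g/n_g)⁻¹u ≤ χ²₂(level)} with Σ̂_g the group's empirical 2-D
score covariance, level 0.99 by default. Percentile exemplars take the
linear-interpolation quantiles of LD1 at 0, 0.1, …, 1 and report the k=5
plants nearest each quantile value, ties broken by plant id.

## Subset selection, bootstrap, permutations

The selection criterion is ζ² = U/(U + r), U = tr(E_S⁻¹H_S), r =
min(|S|, g−1): a [0, 1] normalization of the Hotelling–Lawley trace that
reduces to the squared first canonical correlation when r = 1. Search is
exhaustive over all subsets of each size (feasible to p = 20; beyond
that a greedy forward fallback warns), ties broken by lexicographic
column order; subsets with singular within-scatter are skipped and
counted.

Bootstrap: B = 1000 case resamples with replacement; each replicate
refits the LDA on the selected subset; discriminants are matched across
replicates by eigenvalue order (a documented limitation when eigenvalues
are nearly degenerate) and sign-aligned to the reference fit by dot
product — without this alignment the loading means wash toward zero,
since a discriminant is only defined up to sign. Replicates that lose a
whole group are redrawn and counted. Both the bootstrap sd and sd/√B
are reported; the summary table prints mean (SE) with SE = sd/√B, the
quantity whose ratio to the mean reproduces published loading p-values,
and per-loading p = 2Φ(−|mean|/SE).

Permutation tests: six schemes over the four group codes — all groups
(0,1,2,3); within-pairs [(0,1),(2,3)], [(0,2),(1,3)], [(0,3),(1,2)]; and
(0,1) or (2,3) alone with the other pair held fixed. Labels are
shuffled uniformly within each block, preserving group sizes; the
statistic is ζ² of a *fixed* variable subset (default: the best size-9
subset selected once on the observed labels) against the full four-group
labelling; n = 10 000 permutations by default and p uses the add-one
estimator (1 + #{null ≥ obs})/(1 + n), never zero. Fixing the subset
rather than re-selecting per permutation is slightly anti-conservative
(the subset was chosen to maximize the observed statistic); re-selection
per permutation is available behind `subset=None` plus per-permutation
search but is off by default for cost.

## Numerical choices and degenerate inputs

- Distance cost matrices use the Gram-matrix identity with a relative
  dead-band (cost² < 1e-12 × scale ⇒ 0) so identical curves cost exactly
  0 despite floating-point cancellation.
- Convex hulls of collinear point sets have area 0, not an error.
- Singular E (more variables than within-group degrees of freedom)
  raises with a pointer to subset selection; Mahalanobis with identical
  means returns 0 even when the pooled covariance is singular.
- MDS with fewer positive eigenvalues than requested dimensions raises
  and advises a smaller k.
- Resampled polylines shorten at corners by O(1/m); m = 50 keeps this
  well below between-plant variation.

## Problem sizes used in the test suite

Simulation-backed checks run at reduced but statistically adequate
sizes, chosen as the package's own benchmark design: planted-effect
recovery uses 50 cohorts of 5 plants per cell (85 plants) with 199
permutations per test; type-I calibration uses 200 null datasets of 40
plants with 500 permutations; the full-scale defaults (17 plants per
cell, 10 000 permutations, B = 1000) are exercised by
`scripts/acceptance.py` and the command-line pipeline.

## Known limitations

- The distance measure compares laterals independently of their parent
  seminals and ignores topology beyond the seminal/lateral split; a
  quotient-space tree metric would respect branching structure but is out
  of scope.
- The generator's group effects are exchangeable across lines within a
  group; line-level variation is not modelled, so line-resolved displays
  (heat maps, overlays) show sampling noise plus group effects only.
- ζ² subset search is exhaustive only to moderate p; the greedy fallback
  does not guarantee the optimum.
- Bootstrap discriminant matching by eigenvalue order can mix
  discriminants when eigenvalues cross under resampling.
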