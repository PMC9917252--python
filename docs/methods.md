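# Methods

## Scope and data model

The pipeline consumes localization tables (one row per fitted fluorophore
localization: x, y in nm, acquisition frame, spot intensity in camera A/D
counts) and, optionally, an 8-bit epifluorescence image of the bouton
channel at 126 nm/px used as a mask.  All coordinates use the image
convention (origin top-left, y downward, nm units); density-matrix bins and
mask pixels are half-open intervals, so each localization belongs to
exactly one bin.

Rows with intensity at or below the A/D cutoff (default 12,000) are dropped
at read time.  Both plain-name headers (`x y frame intensity`) and
rapidSTORM attribute-style headers (`<field identifier="Position-0-0" …>`)
are accepted; `frame` and `intensity` are optional (defaults 0 and +∞).

## Two-level clustering

AZ clusters are detected with HDBSCAN (scikit-learn implementation) on raw
x/y.  The AZ-level parameters, minimum cluster size 100 and minimum
samples 20, are configuration defaults calibrated on the synthetic preset
to recover generated AZ counts; they are not literature constants and are
exposed in the config.  Subclusters are detected by a second HDBSCAN run
restricted to each AZ's member points, with the protocol-specific
parameters 24/6 (classical fixation) and 20/5 (HPF/FS).

Two robustness details:

* HDBSCAN's default cluster selection cannot return a single cluster
  covering everything; when no cluster is found the run is repeated
  allowing the tree root, so one tight blob is one subcluster.
* HDBSCAN over a sparse background promotes density fluctuations into
  spurious "clusters" whose members are spaced far above the alpha scale.
  A detected AZ must therefore have at least half of its members covered
  by its α = 800 nm² shape (`min_footprint_coverage`); genuine AZs sit at
  ~100% coverage, Poisson-background artefacts near 0%, so pure-CSR input
  yields no AZs while dense AZs are untouched.

Exclusion filters follow strict inequalities: AZs are excluded when
area < 0.03 µm², area > 0.3 µm², localization count > 8000, or mean density
> 60,000/µm²; boundary values are kept, and each excluded AZ reports the
first violated rule (rules checked in that order).

## Alpha shapes

α is a squared-circumradius criterion in nm² (α = 800 for AZs, 300 for
SCs): Delaunay triangles with circumradius² ≤ α are retained, the area is
their summed area, the boundary the union outline.  α → ∞ recovers the
convex hull; fewer than three or collinear points give area 0 with a
degenerate flag.  Areas are exact sums, so they are monotone in α and
rigid-motion invariant to floating-point tolerance.

## Ripley H function

Per AZ, the uncorrected estimator

    K(r) = A · Σ_{i≠j} 1[d_ij ≤ r] / (n(n−1)),   H(r) = √(K(r)/π) − r

is evaluated on the integer grid r = 0…120 nm, with A the AZ's own
alpha-shape area (configurable; the bounding area convention changes the H
scale, not the ordering of maxima).  No edge correction is applied.
Coincident localizations (blinking duplicates) count at every radius.
Averaging across AZs is unweighted (one AZ, one vote; SD with n−1).  The
reported maximum is the smallest radius attaining the global maximum over
r ∈ (0, 120]; a non-positive maximum returns "no clustering signal".

## NeNA precision

For every localization in frame t the nearest neighbour in frame t+1 is
collected.  The 1-nm-binned distance histogram on [0, 100] nm is fitted
with the same-molecule model p(d) = (d/2σ²)·exp(−d²/4σ²) — the distance
between two independent 2D Gaussian localizations of one emitter, mode at
√2σ — plus a single linear term for different-molecule pairs.  The start
value comes from the median of in-range distances (distant
different-molecule pairs must not steer it).  At least 100 pairs are
required; exact re-localizations (median < 0.05 nm) report σ ≈ 0 without
fitting.

## SNR

Signal is the mean over kept AZs of n_locs / alpha-shape area.  Background
is the density of localizations on the inverse mask (pixel < 80) after
cutting the AZ signal.  The cut removes localizations inside kept-AZ
polygons and cluster members lying on mask-foreground pixels; members that
HDBSCAN absorbed from the extrasynaptic background (a sparse halo of a few
dozen points per AZ) remain, because the image-based cut this mirrors could
never remove extrasynaptic signal, and removing them biases the background
density several percent low.  An all-foreground mask or a zero background
count raises an error (the ratio is undefined).

## Bouton morphometry

Connected mask components (pixel ≥ threshold, default 80) are traced at
sub-pixel precision: the component is lightly Gaussian-smoothed (0.7 px)
and contoured at the 0.5 level.  Circularity 4πA/P² is quadratically
sensitive to perimeter, and a raw marching-squares contour of binary data
overestimates perimeter by several percent (a digital disc would read
~0.91); the smoothed level set reads 0.97 for a 40-px disc and π/4 within
1.5% for a square, while preserving area to <1%.  Note the mask itself
limits accuracy: rasterizing a ~1.3-µm ellipse on a 126-nm binary grid
fluctuates the pixel area by ~±2% with sub-pixel placement, and the ROI
area tracks the mask, not the ideal ellipse.

## Synthetic-data generator

The generator is the test bed standing in for unavailable raw data.  One
AZ = 13 subclusters, each a uniform disc (radius 22 nm HPF-like / 28 nm
PFA-like) emitting 86 localizations, plus unclustered AZ localizations
(fraction 0.25 of the AZ total) uniform over the AZ disc; subcluster
centres are placed with minimum separation 2.2 × radius inside the AZ disc.
Emitters blink: localization counts per emitter are geometric (mean 2.0)
on consecutive frames, and every localization gets independent isotropic
Gaussian error (σ = 6.7 nm HPF-like, 7.0 nm PFA-like).  Fields are chains
of elliptical boutons (semi-axes 1400 × 950 nm, area ≈ 4.2 µm²) containing
well-separated AZs, over homogeneous Poisson background (55 and
74 locs/µm² for the two presets).  All randomness flows through one seeded
`numpy` Generator; outputs are bit-reproducible.

Preset geometry.  The HPF-like AZ radius is 167 nm (disc area 0.088 µm²,
the measured median for cryofixed AZs); localization count
13 × 86/0.75 ≈ 1490 sits inside the measured interquartile range.  Uniform
discs were chosen over Gaussian subclusters so the H maximum has a
well-defined generative radius; the unclustered fraction and separation
factor were calibrated once, at design time, so that the averaged
H-function maximum over many AZs lands on the generative subcluster radius
(the defining property of the H analysis this emulates) — the unclustered
localizations also make the α = 800 nm² shape cover the AZ footprint, as
unassigned localizations do in real data.  The PFA-like preset is the same
geometry scaled by 28/22 (AZ radius 212.5 nm, area 0.143 µm², within the
measured classical-fixation interquartile range), exploiting the scale
equivariance of H.

What the generator does not emulate: dye photophysics beyond geometric
blinking (no dark-state kinetics, no multiple emission bursts per
fluorophore), axial (z) structure, drift, repeated-localization clusters
from antibody stoichiometry, or the continuous Brp scaffold between
subclusters.  Passing tests therefore demonstrate estimator correctness
and parameter recovery in this controlled universe, not performance on
real tissue.

## Study conditions used by the validation suite

Problem sizes are the package's own choices, selected to give stable
statistics at desk scale:

* **H-maximum recovery** — 200 AZs per preset, independent localizations
  (no blinking; duplicate pairs would add a competing H excess near 2σ),
  jitter σ = 3 nm.  Recovered maxima: 22 nm (HPF-like) and 28 nm
  (PFA-like), each within ±2 nm of the generative radius across seeds.
* **Subcluster-count recovery** — 50 AZs of 13 discs with edge gaps
  ~11 nm (separation factor 2.5) and 5% unclustered background, detection
  with (20, 5); the median count is 13.  At the H-calibrated packing
  (touching discs, 25% background) HDBSCAN merges neighbours and the
  median drops to 12 — subcluster counting needs resolvable gaps.
* **NeNA recovery** — 5000 emitters localized in 2–4 consecutive frames,
  σ = 6.7 nm, recovered within ±10%.
* **CSR null** — 100 Poisson patterns of ~2000 points in a 5.8-µm square;
  the mean H stays within ±2 nm of zero up to 60 nm.  The region must not
  be much smaller, or the uncorrected estimator's negative edge bias
  exceeds that band.
* **SNR consistency** — 20 fields with unclustered fraction 0.45, where
  the alpha-shape footprint resolves the true AZ area; measured
  SNR / generative ratio = 1.03.  At the sparser preset the alpha shape
  under-covers the AZ disc (area ratio ~0.89–0.94 depending on blinking,
  holes opening where emitter-site spacing approaches the 28-nm alpha
  radius), and the SNR inherits a +11–16% bias — a known limitation of the
  area estimator at low sampling density, documented rather than hidden.

## Group statistics

Two groups: Shapiro–Wilk on each at 0.05; two-tailed t-test when both pass,
Mann–Whitney rank-sum otherwise.  More than two: Kruskal–Wallis, then
Dunn's comparisons versus a designated control (pooled mean ranks, tie
correction Σ(t³−t)/(12(N−1)), Bonferroni-style adjustment over the number
of comparisons).  Summaries report n, median (25th–75th percentile) and
mean ± SD per metric.

## Known limitations

* Exact permutation invariance of clustering fails on tied
  mutual-reachability distances (blinking duplicates): 1–2 boundary points
  out of ~10⁴ may flip with row order.
* The alpha-shape area underestimates a sparsely sampled footprint (see
  SNR above); per-AZ densities are correspondingly overestimated at low
  sampling.
* The uncorrected H estimator is negatively biased near region edges;
  within-AZ analysis keeps this small, but small regions at large radii
  are unreliable.
* Bouton metrics are limited by 126-nm mask rasterization (~±2% area).
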