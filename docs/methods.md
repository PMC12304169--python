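# Methods

`benthoscan` analyses towed-camera (OFOS) photo surveys of the deep seafloor:
from raw images, navigation and per-image taxon detections to colour-corrected
images, unsupervised habitat classes, area-standardised abundance matrices,
local-Moran hotspot maps and community-structure statistics. A synthetic
survey generator with known ground truth makes the whole chain runnable and
testable at desk scale. This note records the models, the parameters that
matter, and the design decisions taken where the design was genuinely open.

## Synthetic survey model

The generator emulates a two-region campaign: seven straight east-west dives,
three in a shallower "East" region (base depth −2700 m) and four in a deeper
"West" region (−3400 m), giving a 700 m regional depth offset. Along-track
bathymetry is the regional base depth plus feature relief: Gaussian bumps for
seamounts and abyssal hills, and a flat-bottomed notch with steep smoothed
(tanh) walls for the canyon. Feature heights follow the kind of relief seen
on real surveys (a 200 m seamount, 40 m paired hills, a 20 m-deep canyon
500 m across); widths are chosen for realistic aspect ratios — a 200 m-high
abyssal seamount with flank slopes of 10–20° spans on the order of a
kilometre, not a few hundred metres.

The camera fires at a fixed per-dive frequency (0.2 Hz on one dive, 0.07 Hz
on two, 0.1 Hz on the rest) while the platform advances at 0.8 ± 0.1 m/s;
altitude is 4.0 ± 0.5 m (truncated at 0.1 m so footprints stay positive).
Track lengths total ≈13.6 km, which yields ≈1800 images and ≈135 sampling
units — full-campaign structure at a size where every stage (including image
enhancement and clustering) runs in minutes on one CPU.

Taxon counts per image are Poisson with mean intensity × footprint area.
The intensity surface for taxon *j* on a dive is

    lambda_j(s) = base_j(region) * (1 + (f_j - 1) * w(s))

where `w(s) ∈ [0,1]` is the normalised topographic weight (feature crest for
seamounts/hills, Gaussian lobes on the wall positions for canyons) and
`f_j = 4` is the topographic enhancement factor, representing the pronounced
aggregation of megafauna on complex terrain. Thirteen taxon classes are used
with regionally distinct composition: the East is dominated by
structure-formers and trace-makers (Porifera, Lebensspuren, Cnidaria,
Mollusca), the sparse West fauna mostly by Foraminifera, Echinodermata and
Arthropoda. Per-taxon base rates are calibrated once, at configuration-build
time, so that the *realized* regional mean abundances (enhancement included)
equal 0.44 (East) and 0.03 (West) individuals/m² — a 14.7× contrast. The
ground-truth object records the intensity surfaces, the planted hotspot
intervals (where `w ≥ 0.5`) and the realized regional means, which is what
parameter-recovery tests score against.

Images are procedural textures (smooth sediment, bioturbated sediment,
ripples, foraminiferal gravel) degraded by a multiplicative radial vignette,
a greenish colour cast (channel gains 0.85/1.15/1.05), log-normal per-image
brightness jitter and Gaussian noise. What the generator deliberately does
*not* model: photorealistic seafloor appearance, water-column optics,
3-D bathymetry, or any explicit link from POC flux/temperature to intensity
(only region × topography multipliers are exposed, and they are labelled as
such). Tests passing on these images therefore demonstrate the mechanics of
enhancement, feature extraction and clustering — not performance on real
seafloor photographs.

## Image enhancement

Three steps, in order, on chronologically sorted batches of 32 images
(altitude, and hence the degradation pattern, is roughly constant over short
track distances):

1. **Batch z-score.** Mean and standard deviation are computed per pixel and
   channel *across* the batch; `z = (x − mean)/(sd + 1e-6)` is mapped
   affinely from [−3, 3] to [0, 1] with clipping. Per-pixel-across-batch
   statistics were chosen (over per-image) because the step's purpose is to
   remove static spatial patterns — the vignette and the shared cast cancel
   exactly. A zero-variance batch maps to mid-grey.
2. **CLAHE** on an 8×8 tile grid with clip limit 0.01 (standard
   contrast-limited practice), channel-wise, bilinear interpolation between
   tile mappings (scikit-image).
3. **Histogram matching** to a manually chosen reference image (the
   post-CLAHE version of the configured reference; no automatic selection).

A trailing batch of fewer than 2 images is merged into the previous batch.
All outputs are in [0, 1].

## Habitat classification

Images are encoded by a deterministic hand-crafted extractor: per-channel
mean/sd/quantiles, grey-level co-occurrence texture summaries (contrast,
correlation, energy, homogeneity at distances 1 and 3, averaged over four
orientations, hence invariant to 90° rotations) and a downsampled 8×8
intensity grid. CNN embeddings can be registered behind the same interface;
features never depend on batch composition. Feature columns are standardised
before clustering so no block of the vector (e.g. the 64 grid cells)
dominates the Euclidean metric.

K-means (multiple restarts, seeded) assigns substrate classes. Because the
raw within-cluster sum of squares decreases monotonically in k and cannot
itself select a class count, k is chosen as the maximiser of the mean
silhouette over k = 2…20; the full (k, silhouette, WCSS) curve is retained so
an elbow rule can be applied by eye. Cluster exemplars (nearest-to-centroid
first, seeded tie-break) support the human step of assigning semantic
substrate names, which remains out of scope.

## Abundance standardisation

The visual footprint of an image at altitude *h* with opening angles
H = 48°, V = 33° is `(2h·tan(H/2)) × (2h·tan(V/2))`; the vertical (smaller)
axis is taken as the along-track image length (configurable). Each dive is
cut into successive 100 m along-track segments; a trailing remainder shorter
than 50 m is merged into the previous unit, otherwise it forms its own
(shorter) unit. Counts are pooled per unit × taxon and divided by the summed
footprint of the unit's images, giving individuals/m². Abundances are
invariant under uniform duplication of images and detections (double
counting inflates counts and area equally), and on constant-intensity
surveys they decorrelate from observed area even where raw counts track it.
Overlap between successive images is flagged when mean image length strictly
exceeds mean spacing (equality counts as no overlap).

Per-unit covariates are derived from the unit table: slope, topographic
position index and terrain ruggedness by centred finite differences of the
per-unit mean depth (3-unit window); temperature and salinity are supplied
per region (East 2.85 °C, West 2.50 °C by default); longitude is the
centroid longitude.

## Spatial statistics

Sampling units are linked to their k = 6 nearest neighbours by great-circle
distance between centroids (ties broken by ascending unit id), with
row-standardised weights so the spatial lag is the mean neighbour value.
Global Moran's I uses the standard cross-product form (null expectation
−1/(n−1)); a neighbourhood curve recomputes I for k = 1…k_max and suggests
the smallest k where |ΔI| < 0.02 for two consecutive steps, falling back to
6. Local Moran statistics `I_i = z_i · lag_i` (population-sd standardised)
obey the decomposition identity mean(I_i) = global I exactly, which the
tests assert to 1e-10.

Significance is assessed by conditional permutation: unit i's value is held
fixed, the remaining values are permuted among the other units, and the
two-sided pseudo p-value is `(#{|I_perm| ≥ |I_obs|} + 1)/(n_perm + 1)` with
n_perm = 999. Significant units are classified by Moran-scatterplot
quadrant: HH → hotspot, LL → coldspot, HL/LH → outlier. No multiple-testing
correction is applied by default (raw significance is reported, as is usual
for exploratory LISA maps). Cross-dive neighbourhoods are excluded by
default — transects are tens of kilometres apart — and dives with ≤ k units
or zero variance are skipped with a warning. Choropleth display uses
quantile binning into 8 classes (ties to the lowest admissible bin; the bin
count is reduced with a warning when there are fewer distinct values).

Hotspot sensitivity is measured on a dedicated planted-hotspot benchmark:
one 3.5 km West-type dive, flat except a single 40 m hill whose enhanced
interval spans ~4 units amid ~31 background units — compact relative to the
6-neighbour scale. A local-Moran classifier is a cluster detector, not a
spike detector: enhancements much wider than the neighbourhood (or dives
with barely more units than k, like the short seamount dive in the default
survey) are not reliably flagged, which mirrors how such surveys behave in
practice.

## Community statistics

Abundances are fourth-root transformed ("double root" — the square root
applied twice, the standard severe transform; plain square root is available
as an option). Bray-Curtis dissimilarities `Σ|x−y| / Σ(x+y)` are computed on
the transformed matrix; all-zero units carry no compositional information
and are excluded with a logged list. UPGMA (group-average linkage) clusters
the dissimilarity matrix.

ANOSIM ranks all n(n−1)/2 dissimilarities (mid-ranks for ties) and computes
`R = (r̄_between − r̄_within) / (M/2)` with `M = n(n−1)/2`, so R ∈ [−1, 1]
and R = 1 iff every between-group pair is more dissimilar than every
within-group pair. The one-sided p-value permutes group labels (999
permutations, +1 correction); the implementation is cross-checked in the
tests against scikit-bio's ANOSIM and against exhaustive enumeration of all
label splits at n ≤ 8. SIMPER splits the Bray-Curtis numerator per taxon and
averages over all between-group pairs; the contributions sum to the average
between-group dissimilarity exactly (asserted to 1e-12), and are computed on
the same transformed matrix as the dissimilarities. Shannon diversity uses
natural logarithms. Group definition defaults to region (East/West); a
dendrogram cut is available as the alternative route to community groups.

Non-metric MDS minimises Kruskal stress-1 with isotonic disparities
(pool-adjacent-violators on the dissimilarity rank order), running SMACOF
from one classical-scaling start plus 19 random starts (seeded) and keeping
the best; coordinates are centred and rotated to principal axes (stress is
rotation-invariant, so this is display convention only). Environmental and
taxon vectors are fitted envfit-style: the least-squares direction through
the ordination, r² as squared multiple correlation, permutation p by
shuffling the variable across units; zero-variance variables are skipped
with a warning.

## Numerical choices and degenerate inputs

- Geodesy: haversine on a sphere (R = 6371 km) — sub-metre accurate over
  ≤10 km transects. Eastward motion follows the parallel.
- Seeds: every stochastic step takes an explicit seed; per-dive generator
  streams derive from (seed, dive index, purpose) so surveys are
  bit-reproducible.
- Zero-variance guards: constant images pass through CLAHE unchanged;
  zero-variance value vectors are rejected by Moran statistics;
  correlations on variance at float-rounding scale (relative sd ≤ 1e-9) are
  reported as undefined (NaN) rather than computed on noise.
- Detection boxes are 0-based, half-open, within image bounds; along-track
  intervals are 0-based half-open [start, end).

## Problem sizes used in tests and the acceptance script

Monte-Carlo checks use the sizes at which their expectations are sharp
enough to be meaningful while staying at desk scale: regional-mean recovery
averages 20 survey seeds, hotspot sensitivity and decorrelation 10 seeds,
LISA type-I calibration one 200-unit field at 999 permutations, ANOSIM
equivalence exhausts all splits at n ≤ 8. The full-pipeline check runs the
complete default survey (≈1800 images at 128×128, ≈135 units).

## Known limitations

- The default feature extractor is hand-crafted; matching deep-embedding
  cluster quality on real imagery would require plugging in a CNN through
  the extractor registry.
- The synthetic texture classes are far easier to separate than real
  sediment facies; clustering scores on them are mechanics checks only.
- Abundance units are individuals/m²; comparisons across camera geometries
  require consistent footprint conventions (which axis is along-track is
  configurable but must match the platform).
- LISA significance is per-unit and uncorrected; with hundreds of units a
  few false positives per map are expected by construction.
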